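import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neuromethyl.annotation import NeuralFlags
from neuromethyl.datamodel import GeneSetCollection, ValidationError
from neuromethyl.diffmeth import GeneCallSet
from neuromethyl.enrichment import (
    EnrichmentRow,
    chi2_2x2,
    compare_proportions,
    fdr_across_cancers,
    neural_enrichment_test,
    odds_ratio,
    ora,
    paired_t_test,
)


def make_calls(n_hyper, n_tested, n_neural_hyper, n_neural_rest, n_neural_total=None):
    """Universe with controlled neural composition in hyper set and rest."""
    hyper = [f"H{i}" for i in range(n_hyper)]
    rest = [f"R{i}" for i in range(n_tested - n_hyper)]
    flags = {g: i < n_neural_hyper for i, g in enumerate(hyper)}
    flags.update({g: i < n_neural_rest for i, g in enumerate(rest)})
    calls = GeneCallSet(
        hyper_genes=frozenset(hyper),
        hypo_genes=frozenset(),
        tested_genes=frozenset(hyper + rest),
    )
    return calls, NeuralFlags(flags=flags)


class TestChi2:
    def test_hand_computed_2x2(self):
        # 30 neural of 100 in-set vs 186 neural of 1000 background rest
        chi2, p = chi2_2x2(np.array([[30, 70], [186, 814]]))
        assert chi2 == pytest.approx(7.49, abs=0.01)
        assert p == pytest.approx(0.006, abs=0.001)

    def test_independence_gives_zero(self):
        chi2, p = chi2_2x2(np.array([[20, 80], [40, 160]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @given(
        st.integers(1, 200), st.integers(1, 200),
        st.integers(1, 200), st.integers(1, 200),
    )
    @settings(max_examples=300, deadline=None)
    def test_equals_squared_two_proportion_z(self, a, b, c, d):
        """Pearson 2×2 chi-squared is the squared pooled two-proportion z."""
        chi2, _ = chi2_2x2(np.array([[a, b], [c, d]]))
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        pooled = (a + c) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        assert chi2 == pytest.approx(z * z, rel=1e-9)


class TestNeuralEnrichment:
    def test_matches_direct_chi2(self):
        calls, flags = make_calls(100, 1100, 30, 186)
        row = neural_enrichment_test(calls, flags, "hyper", "COAD")
        assert row.n_genes == 100 and row.n_neural == 30
        assert row.pct_neural == pytest.approx(30.0)
        assert row.chi2 == pytest.approx(7.49, abs=0.01)

    def test_background_composition_null(self):
        calls, flags = make_calls(100, 1100, 20, 200)  # both 20% neural
        row = neural_enrichment_test(calls, flags, "hyper")
        assert row.chi2 == pytest.approx(0.0, abs=1e-12)
        assert row.p == pytest.approx(1.0)

    def test_small_expected_cell_uses_fisher(self):
        calls, flags = make_calls(3, 1000, 1, 2)
        with pytest.warns(UserWarning, match="Fisher"):
            row = neural_enrichment_test(calls, flags, "hyper")
        assert row.exact

    def test_synthetic_planted_enrichment_rejects(self, planted_run):
        """40% neural planted among hyper genes vs 20% background."""
        from neuromethyl.diffmeth import aggregate_genes, diff_methylation

        annotation, dataset, truth, flags, _ = planted_run
        table, _ = diff_methylation(dataset)
        calls = aggregate_genes(table, annotation)
        row = neural_enrichment_test(calls, flags, "hyper")
        assert row.p < 1e-6
        assert row.pct_neural == pytest.approx(40.0, abs=5.0)


class TestFdrAcrossCancers:
    def test_single_cancer_fdr_equals_p(self):
        rows = [EnrichmentRow("A", "hyper", 10, 3, 30.0, 1.0, 0.04)]
        out = fdr_across_cancers(rows)
        assert out["fdr"].iloc[0] == pytest.approx(0.04)

    def test_identical_ps_unchanged(self):
        rows = [
            EnrichmentRow(f"C{i}", "hyper", 10, 3, 30.0, 1.0, 0.01) for i in range(16)
        ]
        assert np.allclose(fdr_across_cancers(rows)["fdr"], 0.01)

    def test_stepup_by_hand(self):
        rows = [
            EnrichmentRow(f"C{i}", "hyper", 10, 3, 30.0, 1.0, p)
            for i, p in enumerate([1e-5, 0.03, 0.8])
        ]
        assert np.allclose(fdr_across_cancers(rows)["fdr"], [3e-5, 0.045, 0.8])

    def test_directions_adjusted_separately(self):
        rows = [
            EnrichmentRow("A", "hyper", 10, 3, 30.0, 1.0, 0.01),
            EnrichmentRow("B", "hyper", 10, 3, 30.0, 1.0, 0.04),
            EnrichmentRow("A", "hypo", 10, 3, 30.0, 1.0, 0.02),
        ]
        out = fdr_across_cancers(rows).set_index(["cancer_type", "direction"])["fdr"]
        assert out[("A", "hypo")] == pytest.approx(0.02)
        assert out[("A", "hyper")] == pytest.approx(0.02)  # 0.01*2/1


class TestPairedT:
    def test_hand_computed(self):
        t, df, p = paired_t_test([3, 5, 7], [1, 2, 3])
        assert t == pytest.approx(3 * math.sqrt(3), rel=1e-6)
        assert df == 2
        assert p == pytest.approx(0.035, abs=0.001)

    def test_constant_difference_rejected(self):
        with pytest.raises(ValidationError, match="zero-variance"):
            paired_t_test([2, 3, 4], [1, 2, 3])

    def test_pairing_invariant_to_order(self):
        a, b = [3.0, 5.0, 7.5, 4.0], [1.0, 2.0, 3.0, 3.5]
        perm = [2, 0, 3, 1]
        t1, _, p1 = paired_t_test(a, b)
        t2, _, p2 = paired_t_test([a[i] for i in perm], [b[i] for i in perm])
        assert (t1, p1) == pytest.approx((t2, p2))


class TestOra:
    def test_exact_tail_example(self):
        universe = {f"g{i}" for i in range(20)}
        sets = GeneSetCollection(sets={"S": frozenset(f"g{i}" for i in range(5))})
        query = {"g0", "g1", "g2", "g3", "g10"}  # k=4 overlap
        out = ora(query, sets, universe)
        assert out["p"].iloc[0] == pytest.approx(76 / 15504, rel=1e-12)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        sets = GeneSetCollection(sets={"S": frozenset(["g0", "g1"])})
        out = ora({"g10", "g11"}, sets, universe)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_query_equals_universe_p_one(self):
        universe = {f"g{i}" for i in range(15)}
        sets = GeneSetCollection(sets={"S": frozenset(["g0", "g1", "g2"])})
        out = ora(universe, sets, universe)
        assert out["k"].iloc[0] == out["K"].iloc[0]
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_agrees_with_brute_force_enumeration(self):
        """P(X ≥ k) from explicit pmf summation for N ≤ 30."""
        rng = np.random.default_rng(6)
        for _ in range(25):
            N = int(rng.integers(10, 31))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            members = frozenset(rng.choice(universe, K, replace=False))
            query = frozenset(rng.choice(universe, n, replace=False))
            k = len(members & query)
            out = ora(query, GeneSetCollection(sets={"S": members}), set(universe))
            brute = sum(
                math.comb(K, i) * math.comb(N - K, n - i)
                for i in range(k, min(K, n) + 1)
            ) / math.comb(N, n)
            assert out["p"].iloc[0] == pytest.approx(brute, rel=1e-10)

    def test_query_outside_universe_dropped(self):
        universe = {f"g{i}" for i in range(10)}
        sets = GeneSetCollection(sets={"S": frozenset(["g0"])})
        with pytest.warns(UserWarning, match="outside the universe"):
            out = ora({"g0", "zzz"}, sets, universe)
        assert out["n"].iloc[0] == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            ora({"g0"}, GeneSetCollection(sets={"S": frozenset(["g0"])}), set())


class TestCompareProportions:
    def test_identical_proportions_p_one(self):
        p, diff = compare_proportions(50, 100, 5, 10)
        assert p == pytest.approx(1.0)
        assert diff == pytest.approx(0.0)

    def test_premalignant_vs_cancer_contrast_significant(self):
        # counts reconstructed from printed percentages: 35.8% of 2732
        # premalignant HMGs vs 38.5% of 2624 cancer HMGs neural-related
        p, diff = compare_proportions(978, 2732, 1010, 2624)
        assert p < 0.05
        assert diff < 0

    def test_zero_n_rejected(self):
        with pytest.raises(ValidationError):
            compare_proportions(1, 0, 1, 2)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((20, 10, 10, 20), 4.0),
            ((10, 10, 10, 10), 1.0),
            ((5, 0, 3, 7), (5.5 * 7.5) / (0.5 * 3.5)),  # Haldane correction
        ],
    )
    def test_values(self, cells, expected):
        assert odds_ratio(*cells) == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_undefined(self):
        with pytest.raises(ValidationError):
            odds_ratio(0, 0, 3, 7)


def test_null_enrichment_p_uniform(small_universe):
    """Random hyper sets at background neural rate give uniform p (KS)."""
    _, go, _, truth = small_universe
    from neuromethyl import annotation as ann

    flags = ann.classify(go)
    genes = sorted({f"G{i:06d}" for i in range(1, 1001)})
    tested = frozenset(genes)
    rng = np.random.default_rng(123)
    ps = []
    for _ in range(200):
        hyper = frozenset(rng.choice(genes, size=200, replace=False))
        calls = GeneCallSet(hyper_genes=hyper, hypo_genes=frozenset(), tested_genes=tested)
        ps.append(neural_enrichment_test(calls, flags, "hyper").p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_goodness_of_fit_variant_against_fixed_expectation():
    """GOF option: in-set counts tested against a fixed neural proportion."""
    calls, flags = make_calls(100, 1100, 30, 186)
    row = neural_enrichment_test(calls, flags, "hyper", fixed_background=0.186)
    # (30-18.6)²/18.6 + (70-81.4)²/81.4
    assert row.chi2 == pytest.approx((30 - 18.6) ** 2 / 18.6 + (70 - 81.4) ** 2 / 81.4, rel=1e-9)
    null = neural_enrichment_test(calls, flags, "hyper", fixed_background=0.30)
    assert null.p == pytest.approx(1.0)
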