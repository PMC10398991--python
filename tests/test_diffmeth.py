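import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neuromethyl import synthetic
from neuromethyl.datamodel import ValidationError
from neuromethyl.diffmeth import (
    aggregate_genes,
    bh_adjust,
    beta_to_m,
    call_probes,
    diff_methylation,
    ebayes_moderate,
    estimate_prior,
    fit_probewise,
    m_to_beta,
    moderated_t,
)
from tests.conftest import tiny_annotation, tiny_methylation


# --- independent oracles ---------------------------------------------------

def pooled_t_oracle(x, y):
    """Textbook pooled two-sample t on raw vectors."""
    n1, n2 = len(x), len(y)
    coef = np.mean(x) - np.mean(y)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / d
    se = np.sqrt(s2 * (1 / n1 + 1 / n2))
    t = coef / se
    return coef, s2, d, t, 2 * stats.t.sf(abs(t), d)


def bh_reference(p):
    """Quadratic-time BH: adj_(i) = min_{k ≥ i} m·p_(k)/k."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for i in range(m):
        val = min(m * p[order[k]] / (k + 1) for k in range(i, m))
        adj[order[i]] = min(val, 1.0)
    return np.array(adj)


# --- beta/M transform ------------------------------------------------------

class TestBetaToM:
    @pytest.mark.parametrize(
        "beta,expected", [(0.5, 0.0), (0.8, 2.0), (0.25, -1.585)]
    )
    def test_known_values(self, beta, expected):
        assert beta_to_m(beta, offset=0.0) == pytest.approx(expected, abs=1e-3)

    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
    def test_strictly_increasing(self, b1, b2):
        if b1 == b2:
            return
        lo, hi = sorted([b1, b2])
        assert beta_to_m(lo) < beta_to_m(hi)

    @given(st.floats(0.0, 1.0))
    def test_round_trip(self, b):
        assert m_to_beta(beta_to_m(b)) == pytest.approx(b, abs=1e-9)


# --- probewise fit ---------------------------------------------------------

class TestFitProbewise:
    def test_exact_group_means(self):
        # M-values {0,0} vs {2,2}: beta 0.5 and 0.8 at offset 0
        ds = tiny_methylation(
            {"cg1": [0.8, 0.8, 0.5, 0.5]}, ["tumor", "tumor", "normal", "normal"]
        )
        fit = fit_probewise(ds, offset=0.0)
        assert fit.loc["cg1", "coef"] == pytest.approx(2.0, abs=1e-12)
        assert fit.loc["cg1", "s_sq"] == pytest.approx(0.0, abs=1e-20)
        assert fit.loc["cg1", "mean_dbeta"] == pytest.approx(0.3)

    def test_equal_groups_zero_coef(self):
        ds = tiny_methylation(
            {"cg1": [0.3, 0.6, 0.3, 0.6]}, ["tumor", "tumor", "normal", "normal"]
        )
        assert fit_probewise(ds).loc["cg1", "coef"] == 0.0

    def test_matches_two_sample_oracle(self):
        rng = np.random.default_rng(42)
        beta = rng.uniform(0.05, 0.95, size=(30, 10))
        ds = tiny_methylation(
            {f"cg{i}": beta[i] for i in range(30)}, ["tumor"] * 5 + ["normal"] * 5
        )
        fit = fit_probewise(ds, offset=0.0)
        m = beta_to_m(beta, 0.0)
        for i in range(30):
            coef, s2, d, _, _ = pooled_t_oracle(m[i, :5], m[i, 5:])
            assert fit.iloc[i]["coef"] == pytest.approx(coef, abs=1e-12)
            assert fit.iloc[i]["s_sq"] == pytest.approx(s2, rel=1e-12)
            assert fit.iloc[i]["d"] == d

    def test_probe_with_missingness_uses_complete_cases(self):
        ds = tiny_methylation(
            {"cg1": [0.8, 0.8, np.nan, 0.5, 0.5, 0.5]},
            ["tumor"] * 3 + ["normal"] * 3,
        )
        fit = fit_probewise(ds, offset=0.0)
        assert fit.loc["cg1", "d"] == 3  # 2 + 3 - 2

    def test_probe_below_two_per_group_excluded(self):
        ds = tiny_methylation(
            {
                "cg1": [0.8, np.nan, 0.5, 0.5],
                "cg2": [0.8, 0.7, 0.5, 0.4],
            },
            ["tumor", "tumor", "normal", "normal"],
        )
        with pytest.warns(UserWarning, match="excluded 1 probes"):
            fit = fit_probewise(ds)
        assert list(fit.index) == ["cg2"]


# --- empirical Bayes -------------------------------------------------------

class TestEbayes:
    def test_identical_variances_degenerate_shrinkage(self):
        s2 = np.full(100, 0.7)
        d = np.full(100, 10.0)
        fit = ebayes_moderate(s2, d)
        assert np.isinf(fit.d0)
        assert fit.s0_sq == pytest.approx(0.7, rel=1e-6)
        assert np.allclose(fit.s_post_sq, 0.7)

    def test_d0_zero_is_ordinary_t(self):
        rng = np.random.default_rng(1)
        s2 = rng.chisquare(5, 50)
        d = np.full(50, 8.0)
        coef = rng.normal(size=50)
        unit = np.full(50, np.sqrt(0.4))
        fit = ebayes_moderate(s2, d, d0=0.0)
        t, df, p = moderated_t(coef, unit, fit, d)
        t_ref = coef / np.sqrt(s2 * 0.4)
        assert np.allclose(t, t_ref, rtol=1e-12)
        assert np.allclose(p, 2 * stats.t.sf(np.abs(t_ref), 8), rtol=1e-12)

    def test_posterior_between_sample_and_prior(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(3, 500)
        d = np.full(500, 6.0)
        fit = ebayes_moderate(s2, d)
        lo = np.minimum(s2, fit.s0_sq)
        hi = np.maximum(s2, fit.s0_sq)
        assert np.all(fit.s_post_sq >= lo - 1e-12)
        assert np.all(fit.s_post_sq <= hi + 1e-12)

    def test_zero_variance_probe_gets_positive_posterior(self):
        s2 = np.concatenate([[0.0], np.random.default_rng(3).chisquare(4, 99)])
        fit = ebayes_moderate(s2, np.full(100, 10.0))
        assert fit.d0 > 0
        assert fit.s_post_sq[0] > 0

    def test_few_probes_falls_back_to_ordinary_t(self):
        with pytest.warns(UserWarning, match="no shrinkage"):
            fit = ebayes_moderate(np.array([0.5, 1.0, 2.0]), np.array([4.0, 4.0, 4.0]))
        assert fit.d0 == 0.0

    def test_prior_recovery_single_sim(self):
        """Moment estimator recovers (d0, s0²) from scaled-inv-chi2 draws."""
        rng = np.random.default_rng(7)
        d0_true, s0_true = 4.0, 1.0
        s2 = s0_true * d0_true / rng.chisquare(d0_true, 1000) * rng.chisquare(10, 1000) / 10
        d0_hat, s0_hat = estimate_prior(s2, np.full(1000, 10.0))
        assert d0_hat == pytest.approx(d0_true, abs=1.5)
        assert s0_hat == pytest.approx(s0_true, rel=0.15)


# --- BH --------------------------------------------------------------------

class TestBH:
    def test_hand_worked_stepup(self):
        assert np.allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_single_and_tied(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        assert np.all(bh_adjust(p) >= p)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_quadratic_reference(self, p):
        assert np.allclose(bh_adjust(p), bh_reference(p), rtol=1e-12, atol=1e-12)


# --- calls and aggregation -------------------------------------------------

def _table(rows):
    return pd.DataFrame(
        rows, columns=["p_adj", "logFC_m", "mean_dbeta"],
        index=[f"cg{i}" for i in range(len(rows))],
    )


class TestCallProbes:
    @pytest.mark.parametrize(
        "p_adj,lfc,db,expected",
        [
            (0.01, 1.5, 0.12, "hyper"),
            (0.01, 1.5, 0.10, "ns"),   # boundary dbeta excluded
            (0.06, 3.0, 0.30, "ns"),   # not significant
            (0.01, 1.0, 0.12, "ns"),   # boundary lfc excluded
            (0.05, 1.5, 0.12, "ns"),   # boundary alpha excluded
            (0.01, -1.5, -0.12, "hypo"),
        ],
    )
    def test_three_threshold_rule(self, p_adj, lfc, db, expected):
        calls = call_probes(_table([(p_adj, lfc, db)]))
        assert calls.iloc[0] == expected

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValidationError):
            call_probes(_table([(0.01, 2.0, 0.2)]), alpha=0.0)


class TestAggregateGenes:
    ANNO = tiny_annotation(
        [
            ("cg0", "GA", "TSS200"),
            ("cg1", "GA", "TSS1500"),
            ("cg2", "GA", "Body"),
            ("cg3", "GB", "1stExon"),
            ("cg4", "GB", "TSS200"),
            ("cg5", "GC", "Body"),
        ],
        island={"cg0": 1, "cg1": 0, "cg2": 1, "cg3": 0, "cg4": 1, "cg5": 1},
    )

    def _calls(self, calls):
        t = _table([(0.01, 2.0, 0.2)] * 6)
        t["call"] = calls
        return t

    def test_one_hyper_promoter_probe_suffices(self):
        t = self._calls(["hyper", "ns", "ns", "ns", "ns", "ns"])
        out = aggregate_genes(t, self.ANNO)
        assert out.hyper_genes == {"GA"}
        assert out.tested_genes == {"GA", "GB"}

    def test_both_directions_gene_in_both_sets(self):
        t = self._calls(["hyper", "hypo", "ns", "ns", "ns", "ns"])
        out = aggregate_genes(t, self.ANNO)
        assert "GA" in out.hyper_genes and "GA" in out.hypo_genes

    def test_body_only_probe_never_calls_gene(self):
        t = self._calls(["ns", "ns", "hyper", "ns", "ns", "hyper"])
        out = aggregate_genes(t, self.ANNO)
        assert out.hyper_genes == frozenset()
        assert "GC" not in out.tested_genes

    def test_island_only_restriction(self):
        # GA's only hyper promoter probe (cg1) is off-island
        t = self._calls(["ns", "hyper", "ns", "ns", "ns", "ns"])
        assert aggregate_genes(t, self.ANNO).hyper_genes == {"GA"}
        assert aggregate_genes(t, self.ANNO, island_only=True).hyper_genes == frozenset()

    def test_order_independent(self):
        t = self._calls(["hyper", "ns", "ns", "hypo", "ns", "ns"])
        shuffled = t.iloc[::-1]
        a = aggregate_genes(t, self.ANNO)
        b = aggregate_genes(shuffled, self.ANNO)
        assert (a.hyper_genes, a.hypo_genes, a.tested_genes) == (
            b.hyper_genes, b.hypo_genes, b.tested_genes,
        )


# --- whole-stage properties ------------------------------------------------

def test_stage_equals_oracle_when_unshrunk():
    """With d0 forced to 0 the full stage is the pooled two-sample t."""
    rng = np.random.default_rng(9)
    beta = rng.uniform(0.05, 0.95, size=(50, 12))
    ds = tiny_methylation(
        {f"cg{i:02d}": beta[i] for i in range(50)}, ["tumor"] * 6 + ["normal"] * 6
    )
    table, _ = diff_methylation(ds, offset=0.0, d0=0.0)
    m = beta_to_m(beta, 0.0)
    for i, probe in enumerate(f"cg{i:02d}" for i in range(50)):
        _, _, _, t_ref, p_ref = pooled_t_oracle(m[i, :6], m[i, 6:])
        assert table.loc[probe, "t_mod"] == pytest.approx(t_ref, abs=1e-10)
        assert table.loc[probe, "p"] == pytest.approx(p_ref, abs=1e-10)


def test_hyper_calls_monotone_in_effect_size(small_universe):
    annotation, _, _, truth0 = small_universe
    counts = []
    for effect in [0.5, 1.5, 3.0]:
        ds, _ = synthetic.generate_methylation(
            annotation, truth0, n_hyper=100, effect_m=effect,
            n_normal=8, n_tumor=8, seed=77,
        )
        table, _ = diff_methylation(ds)
        counts.append(int((table["call"] == "hyper").sum()))
    assert counts[0] <= counts[1] <= counts[2]


def test_invariants_on_synthetic_table(planted_run):
    _, dataset, _, _, _ = planted_run
    table, fit = diff_methylation(dataset)
    assert np.all(table["p_adj"] >= table["p"] - 1e-15)
    hyper = table[table["call"] == "hyper"]
    assert (hyper["p_adj"] < 0.05).all()
    assert (hyper["logFC_m"] > 1).all()
    assert (hyper["mean_dbeta"] > 0.1).all()
    assert fit.d0 > 0 and fit.s0_sq > 0
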