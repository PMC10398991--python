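"""Contingency-table statistics for neural-gene enrichment.

The central question — are neural-related genes overrepresented among
promoter-hypermethylated genes relative to the array background? — is
answered with a Pearson chi-squared test (1 df, no continuity correction)
on the 2×2 table (in set vs rest of tested background) × (neural vs not),
BH-corrected across cancer types per direction. A generic upper-tail
hypergeometric overrepresentation test over named gene sets, proportion
comparisons and odds ratios round out the toolbox.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from neuromethyl.annotation import NeuralFlags
from neuromethyl.datamodel import GeneSetCollection, ValidationError
from neuromethyl.diffmeth import GeneCallSet, bh_adjust


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared for a 2×2 table, 1 df, no continuity correction.

    Degenerate tables (a zero margin) return (0, 1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValidationError("need a non-negative 2×2 table")
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        return 0.0, 1.0
    expected = np.outer(rows, cols) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """Odds ratio of [[a, b], [c, d]], Haldane +0.5 applied iff a cell is 0.

    Errors when a full row or column is zero (odds undefined).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValidationError("counts must be non-negative")
    t = cells.reshape(2, 2)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("odds ratio undefined: a zero row or column")
    if np.any(cells == 0):
        a, b, c, d = cells + 0.5
    return float((a * d) / (b * c))


@dataclass
class EnrichmentRow:
    """One cancer type × direction row of the enrichment summary."""

    cancer_type: str
    direction: str  # hyper | hypo
    n_genes: int
    n_neural: int
    pct_neural: float
    chi2: float
    p: float
    fdr: float = np.nan
    exact: bool = False  # Fisher fallback used (an expected cell < 1)

    def as_dict(self) -> dict:
        return {
            "cancer_type": self.cancer_type,
            "direction": self.direction,
            "n_genes": self.n_genes,
            "n_neural": self.n_neural,
            "pct_neural": self.pct_neural,
            "chi2": self.chi2,
            "p": self.p,
            "fdr": self.fdr,
            "exact": self.exact,
        }


def neural_enrichment_test(
    calls: GeneCallSet,
    flags: NeuralFlags,
    direction: str = "hyper",
    cancer_type: str = "NA",
    fixed_background: float | None = None,
) -> EnrichmentRow:
    """Test neural-gene enrichment in the hyper (or hypo) set vs background.

    The background is the rest of the tested genes (genes with ≥1 tested
    promoter probe); the comparison conditions on the genes actually
    assessable on the array. When any expected cell falls below 1 the
    chi-squared approximation is replaced by Fisher's exact test and the
    row is flagged ``exact``. Alternatively, ``fixed_background`` tests the
    in-set neural count against a fixed expected proportion (1-df
    goodness of fit) instead of the 2×2 comparison.
    """
    if direction not in {"hyper", "hypo"}:
        raise ValidationError(f"direction must be hyper or hypo, got {direction!r}")
    if len(calls.tested_genes) < 10:
        raise ValidationError("need ≥10 tested genes for the enrichment test")
    in_set = calls.hyper_genes if direction == "hyper" else calls.hypo_genes
    if not in_set:
        raise ValidationError(f"{direction} gene set is empty")
    rest = calls.tested_genes - in_set
    flagged = flags.flagged()
    a = len(in_set & flagged)
    b = len(in_set) - a
    c = len(rest & flagged)
    d = len(rest) - c
    if fixed_background is not None:
        if not 0 < fixed_background < 1:
            raise ValidationError("fixed_background must lie in (0, 1)")
        expected = np.array([fixed_background, 1 - fixed_background]) * len(in_set)
        chi2, p = stats.chisquare([a, b], expected)
        return EnrichmentRow(
            cancer_type=cancer_type, direction=direction, n_genes=len(in_set),
            n_neural=a, pct_neural=100.0 * a / len(in_set),
            chi2=float(chi2), p=float(p),
        )
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if np.any(expected < 1):
        warnings.warn("expected cell < 1: reporting Fisher exact p", stacklevel=2)
        _, p = stats.fisher_exact(table)
        chi2, exact = np.nan, True
    else:
        chi2, p = chi2_2x2(table)
        exact = False
    return EnrichmentRow(
        cancer_type=cancer_type,
        direction=direction,
        n_genes=len(in_set),
        n_neural=a,
        pct_neural=100.0 * a / len(in_set),
        chi2=chi2,
        p=p,
        exact=exact,
    )


def fdr_across_cancers(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """BH adjustment across cancer types, within each direction.

    Returns the Table-1-style summary (one row per cancer × direction).
    """
    if not rows:
        raise ValidationError("no enrichment rows")
    df = pd.DataFrame([r.as_dict() for r in rows])
    df["fdr"] = np.nan
    for direction, idx in df.groupby("direction").groups.items():
        df.loc[idx, "fdr"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    return df


def paired_t_test(pct_a, pct_b) -> tuple[float, int, float]:
    """Paired two-tailed t-test on per-cancer percentage pairs.

    Returns (t, df, p); errors on degenerate (zero-variance) differences.
    """
    a = np.asarray(pct_a, dtype=float)
    b = np.asarray(pct_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("need ≥3 equal-length pairs")
    diff = a - b
    if np.allclose(diff, diff[0]):
        raise ValidationError("zero-variance paired differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), int(a.size - 1), float(p)


@dataclass
class OraRow:
    """One gene set's overrepresentation result."""

    set_name: str
    k: int  # overlap
    K: int  # set size within universe
    n: int  # query size
    N: int  # universe size
    p: float
    p_adj: float = np.nan


def ora(
    query: frozenset[str] | set[str],
    collection: GeneSetCollection,
    universe: frozenset[str] | set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation over named gene sets.

    ``p = P(X ≥ k)`` with X ~ Hypergeom(N, K, n); BH across sets. Query
    genes outside the universe are dropped with a warning.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = frozenset(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"dropping {len(outside)} query genes outside the universe", stacklevel=2
        )
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for name, members in sorted(collection.items()):
        K = len(members & universe)
        k = len(members & query)
        # P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(OraRow(set_name=name, k=k, K=K, n=n, N=N, p=min(p, 1.0)))
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["p_adj"] < 0.05
    return df


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sample proportion test (chi-squared, 1 df, no correction).

    Returns (two-sided p, difference x1/n1 − x2/n2).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("counts inconsistent with sample sizes")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    _, p = chi2_2x2(table)
    return p, x1 / n1 - x2 / n2
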