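"""Confounder analyses for the neural-hypermethylation signal.

Three checks that the enrichment of neural-related genes among promoter-
hypermethylated genes (HMGs) is not an artifact:

* **Tumor purity** — per-sample mean promoter methylation for four gene
  groups (neural/non-neural × HMG/non-differentially-methylated) regressed
  on the sample's tumor-cell fraction with Huber robust regression
  (M-estimation, tuning constant 1.345, MAD scale — the conventional
  defaults). A positive slope for HMG groups with flat non-DM groups shows
  purity dilutes the signal without creating it.
* **Methylation degree** — do neural HMGs reach higher tumor methylation
  than non-neural HMGs? Compared distributionally by Wilcoxon rank-sum.
* **Bivalency** — cross-tabulation of hypermethylation against bivalent
  chromatin status, overall and stratified by neural status.

Plus hallmark-wise enrichment: within each cancer-hallmark gene set, is the
neural share higher among HMGs than non-HMGs (chi-squared, BH across sets)?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from neuromethyl.annotation import NeuralFlags
from neuromethyl.datamodel import (
    GeneSetCollection,
    MethylationDataset,
    ProbeAnnotation,
    ValidationError,
)
from neuromethyl.diffmeth import GeneCallSet, bh_adjust
from neuromethyl.enrichment import chi2_2x2, odds_ratio

GENE_GROUPS = ("neural_hmg", "nonneural_hmg", "neural_nondm", "nonneural_nondm")


def gene_groups(calls: GeneCallSet, flags: NeuralFlags) -> dict[str, frozenset[str]]:
    """The four purity-analysis gene groups over the tested universe."""
    neural = flags.flagged() & calls.tested_genes
    hmg = calls.hyper_genes
    nondm = calls.tested_genes - calls.hyper_genes - calls.hypo_genes
    return {
        "neural_hmg": hmg & neural,
        "nonneural_hmg": hmg - neural,
        "neural_nondm": nondm & neural,
        "nonneural_nondm": nondm - neural,
    }


def sample_group_means(
    dataset: MethylationDataset,
    calls: GeneCallSet,
    flags: NeuralFlags,
    annotation: ProbeAnnotation,
    group: str = "tumor",
) -> pd.DataFrame:
    """Per-sample mean promoter beta for each of the four gene groups.

    Empty gene groups are omitted with a warning. Returns samples × groups.
    """
    samples = dataset.group_samples(group)
    promoter = annotation.promoter_pairs()
    promoter = promoter[promoter["probe_id"].isin(dataset.beta.index)]
    out = {}
    for name, members in gene_groups(calls, flags).items():
        probes = promoter.loc[promoter["gene_id"].isin(members), "probe_id"].unique()
        if len(probes) == 0:
            warnings.warn(f"gene group {name!r} is empty: omitted", stacklevel=2)
            continue
        out[name] = dataset.beta.loc[probes, samples].mean(axis=0)
    if not out:
        raise ValidationError("all gene groups empty")
    return pd.DataFrame(out)


@dataclass
class PurityModelFit:
    """Huber robust-regression fit of mean methylation on tumor purity."""

    group: str
    slope: float
    intercept: float
    scale: float
    iterations: int
    converged: bool


def robust_fit(
    y, x, group: str = "NA", tol: float = 1e-8, maxiter: int = 50
) -> PurityModelFit:
    """Huber M-estimation of ``y = intercept + slope·x`` via IRLS.

    Tuning constant 1.345, MAD residual scale. Samples with missing purity
    are dropped; requires ≥5 usable samples and non-constant x. Errors on
    non-convergence with the iteration count in the message.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    if len(y) < 5:
        raise ValidationError(f"need ≥5 samples with purity, got {len(y)}")
    if np.ptp(x) == 0:
        raise ValidationError("purity is constant: design rank-deficient")
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345))
    res = model.fit(conv="coefs", tol=tol, maxiter=maxiter, scale_est="mad")
    history = getattr(res, "fit_history", {}) or {}
    params_hist = history.get("params", [])
    iterations = len(params_hist)
    converged = True
    if iterations >= maxiter and len(params_hist) >= 2:
        last_change = float(np.max(np.abs(params_hist[-1] - params_hist[-2])))
        if last_change > tol:
            raise ValidationError(
                f"robust fit did not converge in {maxiter} iterations "
                f"(last coefficient change {last_change:.3g})"
            )
    return PurityModelFit(
        group=group,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        scale=float(res.scale),
        iterations=iterations,
        converged=converged,
    )


def purity_regression(
    dataset: MethylationDataset,
    calls: GeneCallSet,
    flags: NeuralFlags,
    annotation: ProbeAnnotation,
) -> pd.DataFrame:
    """Per-group Huber regression of mean promoter methylation on purity."""
    means = sample_group_means(dataset, calls, flags, annotation)
    purity = dataset.samples.loc[means.index, "purity"]
    rows = []
    for name in means.columns:
        fit = robust_fit(means[name].to_numpy(), purity.to_numpy(), group=name)
        rows.append(fit.__dict__)
    return pd.DataFrame(rows)


def methylation_degree_compare(
    dataset: MethylationDataset,
    calls: GeneCallSet,
    flags: NeuralFlags,
    annotation: ProbeAnnotation,
) -> dict:
    """Compare tumor methylation degrees of neural vs non-neural HMGs.

    Per-gene mean tumor beta over promoter probes; two-sided Wilcoxon
    rank-sum between the neural and non-neural HMG sets. Single-gene sets
    are uninformative and flagged (p forced to 1).
    """
    groups = gene_groups(calls, flags)
    neural_set, other_set = groups["neural_hmg"], groups["nonneural_hmg"]
    if not neural_set or not other_set:
        raise ValidationError("both HMG sets must be non-empty")
    tumor = dataset.group_samples("tumor")
    promoter = annotation.promoter_pairs()
    promoter = promoter[promoter["probe_id"].isin(dataset.beta.index)]
    probe_mean = dataset.beta[tumor].mean(axis=1)
    per_gene = (
        promoter.assign(beta=probe_mean.reindex(promoter["probe_id"]).to_numpy())
        .groupby("gene_id")["beta"]
        .mean()
    )
    a = per_gene.reindex(sorted(neural_set)).dropna().to_numpy()
    b = per_gene.reindex(sorted(other_set)).dropna().to_numpy()
    degenerate = len(a) < 2 or len(b) < 2
    if degenerate:
        p = 1.0
        stat = np.nan
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "n_neural": len(a),
        "n_nonneural": len(b),
        "mean_beta_neural": float(np.mean(a)) if len(a) else np.nan,
        "mean_beta_nonneural": float(np.mean(b)) if len(b) else np.nan,
        "direction": "neural_higher"
        if len(a) and len(b) and np.mean(a) > np.mean(b)
        else "neural_not_higher",
        "statistic": float(stat) if stat == stat else np.nan,
        "p": float(p),
        "degenerate": degenerate,
    }


def _crosstab_row(stratum: str, in_rows: frozenset, in_cols: frozenset, universe: frozenset):
    a = len(in_rows & in_cols)
    b = len(in_rows - in_cols)
    c = len((universe - in_rows) & in_cols)
    d = len(universe - in_rows - in_cols)
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p = chi2_2x2(table)
    try:
        orr = odds_ratio(a, b, c, d)
    except ValidationError:
        orr = np.nan
    assert int(table.sum()) == len(universe)
    return {"stratum": stratum, "a": a, "b": b, "c": c, "d": d, "chi2": chi2, "p": p, "odds_ratio": orr}


def bivalency_crosstab(
    calls: GeneCallSet,
    flags: NeuralFlags,
    bivalent: frozenset[str] | set[str],
    universe: frozenset[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate hypermethylation against bivalency and neural status.

    Emits (i) hyper × bivalent over the whole universe, and (ii) hyper ×
    neural within the bivalent and non-bivalent strata. Bivalent genes
    outside the universe are dropped; empty strata are skipped with a
    warning. Rows carry the 2×2 cells (a: both, b: row-only, c: col-only,
    d: neither), chi-squared p and odds ratio.
    """
    universe = frozenset(universe if universe is not None else calls.tested_genes)
    bivalent = frozenset(bivalent) & universe
    hyper = calls.hyper_genes & universe
    neural = flags.flagged() & universe
    rows = []
    if bivalent:
        rows.append(_crosstab_row("overall_hyper_x_bivalent", hyper, bivalent, universe))
    else:
        warnings.warn("no bivalent genes in universe: overall stratum skipped", stacklevel=2)
    for name, stratum in (("within_bivalent", bivalent), ("within_nonbivalent", universe - bivalent)):
        if not stratum:
            warnings.warn(f"stratum {name!r} empty: skipped", stacklevel=2)
            continue
        rows.append(_crosstab_row(f"{name}_hyper_x_neural", hyper & stratum, neural & stratum, stratum))
    return pd.DataFrame(rows)


def hallmark_enrichment(
    calls: GeneCallSet, flags: NeuralFlags, hallmarks: GeneSetCollection
) -> pd.DataFrame:
    """Neural-share enrichment in HMGs vs non-HMGs per hallmark set.

    Each hallmark is restricted to the tested universe; the 2×2 is
    (HMG vs non-HMG) × (neural vs not) with chi-squared p, BH across
    hallmarks. Hallmarks with no tested genes yield an NA row.
    """
    tested = calls.tested_genes
    neural = flags.flagged()
    rows = []
    for name, members in sorted(hallmarks.items()):
        sub = frozenset(members) & tested
        if not sub:
            warnings.warn(f"hallmark {name!r} has no tested genes", stacklevel=2)
            rows.append(
                {"hallmark": name, "n": 0, "a": np.nan, "b": np.nan, "c": np.nan,
                 "d": np.nan, "neural_share_hmg": np.nan,
                 "neural_share_nonhmg": np.nan, "chi2": np.nan, "p": np.nan}
            )
            continue
        hmg = calls.hyper_genes & sub
        nonhmg = sub - calls.hyper_genes
        a = len(hmg & neural)
        b = len(hmg - neural)
        c = len(nonhmg & neural)
        d = len(nonhmg - neural)
        chi2, p = chi2_2x2(np.array([[a, b], [c, d]], dtype=float))
        rows.append(
            {
                "hallmark": name,
                "n": len(sub),
                "a": a, "b": b, "c": c, "d": d,
                "neural_share_hmg": a / (a + b) if a + b else np.nan,
                "neural_share_nonhmg": c / (c + d) if c + d else np.nan,
                "chi2": chi2,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
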