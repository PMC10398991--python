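"""Differential expression for the neural-differentiation contrast.

Each gene's log expression is modelled linearly on condition plus optional
age (linear) and sex (two-level factor) covariates; the condition
coefficient is tested with the same empirical-Bayes moderated t used for
methylation. For log-scaled count matrices, optional precision weights are
derived voom-style from a lowess fit of sqrt residual standard deviation
against mean log expression, evaluated at each observation's fitted value.

Genes with logFC > 1 and BH-adjusted p < 0.05 are upregulated (UR);
mirrored for downregulated (DR). The UR genes of the neurons-vs-progenitors
contrast are the "differentiation-associated" set, whose coupling with
promoter hypermethylation is quantified by :func:`overlap_stats`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from neuromethyl.annotation import NeuralFlags
from neuromethyl.datamodel import ExpressionDataset, ValidationError
from neuromethyl.diffmeth import GeneCallSet, bh_adjust, ebayes_moderate, moderated_t
from neuromethyl.enrichment import chi2_2x2, odds_ratio


def build_design(
    samples: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: tuple[str, ...] = (),
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, condition indicator, then covariates.

    The condition column is 1 for ``contrast[0]`` and 0 for ``contrast[1]``
    (so the coefficient is contrast[0] − contrast[1]); numeric covariates
    enter centred, categorical ones as dummy columns dropping the first
    level. Errors on a rank-deficient design, naming the aliased columns.
    """
    cond = samples["condition"].astype(str)
    keep = cond.isin(contrast)
    if not keep.all():
        raise ValidationError("samples outside the contrast must be subset out first")
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(samples)),
        "condition": (cond == contrast[0]).to_numpy(float),
    }
    for cov in covariates:
        if cov not in samples.columns:
            raise ValidationError(f"covariate {cov!r} missing from sample sheet")
        v = samples[cov]
        if pd.api.types.is_numeric_dtype(v):
            cols[cov] = v.to_numpy(float) - float(v.mean())
        else:
            levels = sorted(v.astype(str).unique())
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (v.astype(str) == lev).to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValidationError(f"rank-deficient design; aliased columns: {aliased}")
    return X, names


def _fit_common_design(Y: np.ndarray, X: np.ndarray, coef_idx: int):
    """OLS of every row of Y on the shared design X."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    coefs = Y @ pinv.T  # genes × p
    fitted = coefs @ X.T
    resid = Y - fitted
    df = n - p
    s_sq = (resid**2).sum(axis=1) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    stderr_unit = float(np.sqrt(xtx_inv[coef_idx, coef_idx]))
    return coefs[:, coef_idx], np.full(len(Y), stderr_unit), s_sq, float(df), fitted


def _fit_weighted(Y: np.ndarray, X: np.ndarray, W: np.ndarray, coef_idx: int):
    """Per-gene weighted least squares (weights differ per observation)."""
    n, p = X.shape
    n_genes = Y.shape[0]
    coef = np.empty(n_genes)
    stderr_unit = np.empty(n_genes)
    s_sq = np.empty(n_genes)
    df = float(n - p)
    for g in range(n_genes):
        w = W[g]
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = Y[g] * sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        s_sq[g] = float(resid @ resid) / df
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        coef[g] = beta[coef_idx]
        stderr_unit[g] = np.sqrt(xtx_inv[coef_idx, coef_idx])
    return coef, stderr_unit, s_sq, df


def voom_weights(
    Y: np.ndarray, X: np.ndarray, span: float = 0.5
) -> np.ndarray:
    """Precision weights from the mean–variance trend of log-count data.

    Fits each gene unweighted, lowess-smooths sqrt residual sd against mean
    log expression, evaluates the trend at each observation's fitted value
    and returns ``predicted_sd**-4`` as the weight matrix (genes × samples).
    """
    _, _, s_sq, _, fitted = _fit_common_design(Y, X, 0)
    mean_expr = Y.mean(axis=1)
    sqrt_sd = np.sqrt(np.sqrt(np.maximum(s_sq, 1e-12)))
    trend = lowess(sqrt_sd, mean_expr, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    pred_sqrt_sd = np.interp(fitted, tx, ty)
    return pred_sqrt_sd**-4


def de_expression(
    dataset: ExpressionDataset,
    contrast: tuple[str, str] = ("neuron", "progenitor"),
    covariates: tuple[str, ...] = (),
    use_precision_weights: bool | None = None,
    alpha: float = 0.05,
    lfc: float = 1.0,
    d0: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression table for one contrast.

    Returns a DataFrame indexed by gene with columns ``logFC``, ``t_mod``,
    ``p``, ``p_adj`` and ``status`` ∈ {UR, DR, nonDE}. Precision weights
    default to ``dataset.is_counts``.
    """
    if use_precision_weights is None:
        use_precision_weights = dataset.is_counts
    keep = dataset.samples["condition"].astype(str).isin(contrast)
    samples = dataset.samples[keep]
    if (samples["condition"] == contrast[0]).sum() < 3 or (
        samples["condition"] == contrast[1]
    ).sum() < 3:
        raise ValidationError("need ≥3 samples per condition")
    Y = dataset.log_expr[samples.index].to_numpy(float)
    X, names = build_design(samples, contrast, covariates)
    coef_idx = names.index("condition")

    if use_precision_weights:
        W = voom_weights(Y, X)
        coef, stderr_unit, s_sq, df = _fit_weighted(Y, X, W, coef_idx)
    else:
        coef, stderr_unit, s_sq, df, _ = _fit_common_design(Y, X, coef_idx)

    d = np.full(len(coef), df)
    fit = ebayes_moderate(s_sq, d, d0=d0)
    t, _, p = moderated_t(coef, stderr_unit, fit, d)
    p_adj = bh_adjust(p)
    status = np.where(
        (p_adj < alpha) & (coef > lfc),
        "UR",
        np.where((p_adj < alpha) & (coef < -lfc), "DR", "nonDE"),
    )
    return pd.DataFrame(
        {"logFC": coef, "t_mod": t, "p": p, "p_adj": p_adj, "status": status},
        index=dataset.log_expr.index,
    )


def classify_differentiation(de: pd.DataFrame) -> frozenset[str]:
    """Differentiation-associated genes: the UR set of the contrast."""
    ur = frozenset(de.index[de["status"] == "UR"])
    if not ur:
        warnings.warn("no upregulated genes: empty differentiation set", stacklevel=2)
    return ur


@dataclass
class OverlapReport:
    """Hypermethylation–differentiation coupling statistics.

    ``shares`` quantifies the hypermethylated share within gene groups
    against the rest of the tested universe; ``expression_composition``
    gives the DR/UR/nonDE split of hypermethylated neural genes by
    differentiation status, with an odds ratio for downregulation.
    """

    shares: pd.DataFrame
    expression_composition: pd.DataFrame


def _share_row(name: str, group: frozenset[str], hyper: frozenset[str], universe: frozenset[str]):
    rest = universe - group
    a = len(group & hyper)
    b = len(group) - a
    c = len(rest & hyper)
    d = len(rest) - c
    chi2, p = chi2_2x2(np.array([[a, b], [c, d]]))
    try:
        orr = odds_ratio(a, b, c, d)
    except ValidationError:
        orr = np.nan
    return {
        "group": name,
        "n": len(group),
        "n_hyper": a,
        "hyper_share_pct": 100.0 * a / len(group) if group else np.nan,
        "odds_ratio": orr,
        "chi2": chi2,
        "p": p,
    }


def overlap_stats(
    hmg: GeneCallSet,
    diff_assoc: frozenset[str] | set[str],
    flags: NeuralFlags,
    de_cancer: pd.DataFrame | None = None,
) -> OverlapReport:
    """Couple promoter hypermethylation to differentiation and expression.

    All sets are intersected with the tested-gene universe first. When a
    cancer DE table is supplied, the expression composition compares
    hypermethylated neural genes inside vs outside the differentiation set.
    """
    universe = hmg.tested_genes
    diff_assoc = frozenset(diff_assoc) & universe
    neural = flags.flagged() & universe
    hyper = hmg.hyper_genes

    rows = []
    if diff_assoc:
        rows.append(_share_row("diff_assoc", diff_assoc, hyper, universe))
        both = diff_assoc & neural
        if both:
            rows.append(_share_row("diff_assoc_and_neural", both, hyper, universe))
        else:
            warnings.warn("empty diff_assoc ∩ neural intersection", stacklevel=2)
    else:
        warnings.warn("empty differentiation set after universe restriction", stacklevel=2)
    shares = pd.DataFrame(rows)

    comp_rows = []
    if de_cancer is not None:
        groups = {
            "hyper_neural_diff": hyper & neural & diff_assoc,
            "hyper_neural_nondiff": (hyper & neural) - diff_assoc,
        }
        counts = {}
        for name, members in groups.items():
            status = de_cancer["status"].reindex(sorted(members)).dropna()
            n = len(status)
            c = status.value_counts()
            counts[name] = (int(c.get("DR", 0)), n)
            comp_rows.append(
                {
                    "group": name,
                    "n": n,
                    "frac_DR": c.get("DR", 0) / n if n else np.nan,
                    "frac_UR": c.get("UR", 0) / n if n else np.nan,
                    "frac_nonDE": c.get("nonDE", 0) / n if n else np.nan,
                }
            )
        (a, n1), (c, n2) = counts["hyper_neural_diff"], counts["hyper_neural_nondiff"]
        if n1 and n2:
            try:
                or_dr = odds_ratio(a, n1 - a, c, n2 - c)
            except ValidationError:
                or_dr = np.nan
            _, p_dr = chi2_2x2(np.array([[a, n1 - a], [c, n2 - c]]))
        else:
            or_dr, p_dr = np.nan, np.nan
            warnings.warn("empty expression-composition group", stacklevel=2)
        for row in comp_rows:
            row["or_DR_diff_vs_nondiff"] = or_dr
            row["p_DR"] = p_dr
    return OverlapReport(shares=shares, expression_composition=pd.DataFrame(comp_rows))
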