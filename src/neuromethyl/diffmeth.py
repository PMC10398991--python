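"""Per-probe differential methylation with empirical-Bayes moderated t.

Testing is done on M-values, ``M = log2((beta + offset) / (1 - beta +
offset))``, whose roughly Gaussian behaviour suits linear modelling; effect
sizes for the biological filter are kept on the beta scale. Per-probe
variances are shrunk toward a common prior by moment matching of log sample
variances to a scaled F distribution (prior df ``d0`` and prior variance
``s0²`` estimated by digamma/trigamma inversion), giving the moderated
t-statistic with ``d0 + d`` degrees of freedom.

A probe is called hypermethylated when BH-adjusted p < alpha, logFC(M) >
lfc and mean Δbeta > dbeta (tumor − normal; strict inequalities);
hypomethylated mirrors with negated cutoffs. A gene is hypermethylated when
at least one of its promoter probes is; genes with both hyper- and
hypomethylated promoter probes belong to both sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from neuromethyl.datamodel import (
    PROMOTER_LABELS,
    MethylationDataset,
    ProbeAnnotation,
    ValidationError,
)

DEFAULT_OFFSET = 1e-6


def beta_to_m(beta, offset: float = DEFAULT_OFFSET):
    """Convert methylation fractions to M-values (log2 ratio scale)."""
    beta = np.asarray(beta, dtype=float)
    return np.log2((beta + offset) / (1.0 - beta + offset))


def m_to_beta(m, offset: float = DEFAULT_OFFSET):
    """Inverse of :func:`beta_to_m`."""
    r = np.exp2(np.asarray(m, dtype=float))
    return (r * (1.0 + offset) - offset) / (1.0 + r)


@dataclass
class EbayesFit:
    """Empirical-Bayes variance shrinkage hyperparameters.

    ``d0`` is the prior degrees of freedom (np.inf when all variances are
    pooled to the prior), ``s0_sq`` the prior variance; ``s_post_sq`` holds
    the per-probe posterior variances (d0*s0² + d*s²)/(d0 + d).
    """

    d0: float
    s0_sq: float
    s_post_sq: np.ndarray


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def estimate_prior(s_sq: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Estimate (d0, s0²) by moment matching on log sample variances.

    Matches the mean and variance of ``log(s²)`` to those implied by
    ``s² ~ s0² · F(d, d0)``; the variance equation is inverted through the
    trigamma function. Returns ``d0 = inf`` when the observed spread of
    log variances does not exceed its sampling expectation.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d = np.asarray(d, dtype=float)
    ok = (s_sq > 0) & (d > 0)
    if ok.sum() < 2:
        raise ValidationError("need at least 2 positive variances to fit the prior")
    z = np.log(s_sq[ok])
    if np.ptp(z) == 0:
        # exactly identical variances: no sampling spread to de-bias;
        # the prior is the common value and shrinkage is total
        return np.inf, float(np.exp(z[0]))
    e = z - special.digamma(d[ok] / 2.0) + np.log(d[ok] / 2.0)
    emean = float(np.mean(e))
    evar = float(np.sum((e - emean) ** 2) / max(len(e) - 1, 1))
    evar -= float(np.mean(special.polygamma(1, d[ok] / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def ebayes_moderate(
    s_sq: np.ndarray, d: np.ndarray, d0: float | None = None, s0_sq: float | None = None
) -> EbayesFit:
    """Shrink per-probe variances toward the estimated prior.

    ``d0``/``s0_sq`` may be forced (``d0=0`` gives the ordinary-t limit).
    With fewer than 10 probes the prior is not estimable with any
    stability, so the fit falls back to no shrinkage with a warning.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(s_sq < 0) or np.any(d < 1):
        raise ValidationError("require s² ≥ 0 and residual df ≥ 1")
    if d0 is None:
        if len(s_sq) < 10 or (s_sq > 0).sum() < 2:
            warnings.warn(
                "too few probes (or positive variances) to fit the prior: "
                "falling back to ordinary t (no shrinkage)",
                stacklevel=2,
            )
            d0, s0_sq = 0.0, float(np.mean(s_sq[s_sq > 0])) if np.any(s_sq > 0) else 1.0
        else:
            est_d0, est_s0 = estimate_prior(s_sq, d)
            d0 = est_d0
            if s0_sq is None:
                s0_sq = est_s0
    elif s0_sq is None:
        s0_sq = float(np.mean(s_sq)) if d0 > 0 else 0.0
    if np.isinf(d0):
        s_post = np.full_like(s_sq, s0_sq)
    elif d0 == 0:
        s_post = s_sq.copy()
    else:
        s_post = (d0 * s0_sq + d * s_sq) / (d0 + d)
    return EbayesFit(d0=float(d0), s0_sq=float(s0_sq), s_post_sq=s_post)


def moderated_t(
    coef: np.ndarray, stderr_unit: np.ndarray, fit: EbayesFit, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t-statistics, total df and two-sided p-values."""
    coef = np.asarray(coef, dtype=float)
    d = np.asarray(d, dtype=float)
    se = np.sqrt(fit.s_post_sq) * np.asarray(stderr_unit, dtype=float)
    t = np.zeros_like(coef)
    nz = se > 0
    t[nz] = coef[nz] / se[nz]
    degenerate = ~nz & (coef != 0)
    t[degenerate] = np.sign(coef[degenerate]) * np.inf
    df_total = d + fit.d0
    if np.isinf(fit.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, df_total, p


def fit_probewise(
    dataset: MethylationDataset,
    offset: float = DEFAULT_OFFSET,
    tumor_group: str = "tumor",
    normal_group: str = "normal",
) -> pd.DataFrame:
    """Per-probe two-group fit of M-values (tumor − normal).

    Missing beta entries are handled complete-case per probe; probes left
    with fewer than 2 observations in either group are excluded (their
    count is reported via a warning).

    Returns a DataFrame indexed by probe with columns ``coef`` (difference
    of group mean M), ``stderr_unit`` (sqrt(1/n1 + 1/n2)), ``s_sq`` (pooled
    residual variance), ``d`` (residual df) and ``mean_dbeta`` (difference
    of group mean beta).
    """
    tumor = dataset.group_samples(tumor_group)
    normal = dataset.group_samples(normal_group)
    if len(tumor) < 2 or len(normal) < 2:
        raise ValidationError(
            f"need ≥2 samples per group; got {len(tumor)} {tumor_group}, "
            f"{len(normal)} {normal_group}"
        )
    bt = dataset.beta[tumor].to_numpy(dtype=float)
    bn = dataset.beta[normal].to_numpy(dtype=float)
    mt = beta_to_m(bt, offset)
    mn = beta_to_m(bn, offset)

    n1 = np.sum(~np.isnan(mt), axis=1)
    n2 = np.sum(~np.isnan(mn), axis=1)
    usable = (n1 >= 2) & (n2 >= 2)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} probes with <2 observations per group", stacklevel=2
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_t = np.nanmean(mt, axis=1)
        mean_n = np.nanmean(mn, axis=1)
        var_t = np.nanvar(mt, axis=1, ddof=1)
        var_n = np.nanvar(mn, axis=1, ddof=1)
        dbeta = np.nanmean(bt, axis=1) - np.nanmean(bn, axis=1)

    d = n1 + n2 - 2
    with np.errstate(invalid="ignore"):
        s_sq = ((n1 - 1) * var_t + (n2 - 1) * var_n) / d
        stderr_unit = np.sqrt(1.0 / n1 + 1.0 / n2)

    out = pd.DataFrame(
        {
            "coef": mean_t - mean_n,
            "stderr_unit": stderr_unit,
            "s_sq": s_sq,
            "d": d.astype(float),
            "mean_dbeta": dbeta,
        },
        index=dataset.beta.index,
    )
    return out[usable]


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ≤ 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_probes(
    table: pd.DataFrame, alpha: float = 0.05, lfc: float = 1.0, dbeta: float = 0.1
) -> pd.Series:
    """Three-threshold hyper/hypo/ns calls (strict inequalities)."""
    if alpha <= 0 or lfc <= 0 or dbeta <= 0:
        raise ValidationError("thresholds must be positive")
    sig = table["p_adj"] < alpha
    hyper = sig & (table["logFC_m"] > lfc) & (table["mean_dbeta"] > dbeta)
    hypo = sig & (table["logFC_m"] < -lfc) & (table["mean_dbeta"] < -dbeta)
    call = pd.Series("ns", index=table.index, name="call")
    call[hyper] = "hyper"
    call[hypo] = "hypo"
    return call


def diff_methylation(
    dataset: MethylationDataset,
    offset: float = DEFAULT_OFFSET,
    alpha: float = 0.05,
    lfc: float = 1.0,
    dbeta: float = 0.1,
    d0: float | None = None,
    tumor_group: str = "tumor",
    normal_group: str = "normal",
) -> tuple[pd.DataFrame, EbayesFit]:
    """Full per-probe differential methylation table.

    Returns the table (columns ``logFC_m``, ``mean_dbeta``, ``t_mod``,
    ``df_total``, ``p``, ``p_adj``, ``call``) and the variance-shrinkage
    fit. ``d0`` may be forced (0 disables shrinkage) for oracle checks.
    """
    base = fit_probewise(dataset, offset, tumor_group, normal_group)
    fit = ebayes_moderate(base["s_sq"].to_numpy(), base["d"].to_numpy(), d0=d0)
    t, df_total, p = moderated_t(
        base["coef"].to_numpy(), base["stderr_unit"].to_numpy(), fit, base["d"].to_numpy()
    )
    table = pd.DataFrame(
        {
            "logFC_m": base["coef"],
            "mean_dbeta": base["mean_dbeta"],
            "t_mod": t,
            "df_total": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=base.index,
    )
    table["call"] = call_probes(table, alpha=alpha, lfc=lfc, dbeta=dbeta)
    return table, fit


@dataclass
class GeneCallSet:
    """Promoter-level gene calls.

    ``tested_genes`` is the background: genes with ≥1 tested promoter
    probe. A gene with both hyper- and hypomethylated promoter probes is a
    member of both ``hyper_genes`` and ``hypo_genes``.
    """

    hyper_genes: frozenset[str]
    hypo_genes: frozenset[str]
    tested_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not (self.hyper_genes | self.hypo_genes) <= self.tested_genes:
            raise ValidationError("called genes must be a subset of tested genes")


def aggregate_genes(
    table: pd.DataFrame,
    annotation: ProbeAnnotation,
    promoter_labels: frozenset[str] = PROMOTER_LABELS,
    island_only: bool = False,
) -> GeneCallSet:
    """Aggregate probe calls to genes via promoter probes.

    A gene is hyper(hypo)methylated iff ≥1 of its promoter probes —
    restricted to CpG-island probes when ``island_only`` — is called
    hyper (hypo). Region labels are taken per (probe, gene) pair, so a
    probe promoter for one gene and body for another counts only for the
    former.
    """
    pairs = annotation.promoter_pairs(promoter_labels, island_only=island_only)
    pairs = pairs[pairs["probe_id"].isin(table.index)]
    calls = table["call"].reindex(pairs["probe_id"]).to_numpy()
    tested = frozenset(pairs["gene_id"])
    hyper = frozenset(pairs["gene_id"].to_numpy()[calls == "hyper"])
    hypo = frozenset(pairs["gene_id"].to_numpy()[calls == "hypo"])
    return GeneCallSet(hyper_genes=hyper, hypo_genes=hypo, tested_genes=tested)
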