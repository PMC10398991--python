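"""Seeded synthetic fixtures with planted ground truth.

The generator emulates the statistical structure of an array methylation
study: a gene universe with promoter/body probes and CpG-island flags, GO
annotations whose term names do or do not contain neural pattern strings
(so the string classifier's answer is decidable by construction), a
two-group beta matrix with logit-normal probe noise and planted promoter
hyper-/hypomethylation, an optional tumor-purity mixture, and a log-scale
expression matrix with a differentiation contrast plus age/sex covariates.

Noise model: per-probe baseline M-values are Gaussian; per-probe noise
variances follow a scaled inverse-chi-squared law so the empirical-Bayes
variance estimator has genuine heterogeneity to shrink. Purity mixing
happens on the beta scale (a cell-fraction mixture of methylation
proportions), not the M scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from neuromethyl.annotation import NEURAL_PATTERNS
from neuromethyl.datamodel import (
    GeneSetCollection,
    GoAnnotation,
    MethylationDataset,
    ProbeAnnotation,
    ExpressionDataset,
    ValidationError,
)

# --- generator defaults (documented in docs/methods.md) -------------------
BASELINE_M_SD = 2.0        # spread of per-probe baseline M-values around 0
NOISE_PRIOR_DF = 4.0       # d0 of the scaled-inv-chi2 law on probe variances
NOISE_PRIOR_VAR = 0.25     # s0² of that law (typical M-value sd ≈ 0.5)
PLANTED_BASELINE_M = 2.0   # |baseline M| of planted probes (pre-shift mode)
PLANTED_BASELINE_SD = 1.0  # spread of planted-probe baselines

#: GO term names containing at least one neural pattern string.
_NEURAL_TERM_NAMES = (
    "axon guidance",
    "regulation of nervous system development",
    "neuron differentiation",
    "synaptic vesicle cycle",
    "brain development",
    "memory consolidation",
    "hippocampus development",
    "dendritic spine morphogenesis",
    "learning or conditioning",
    "neurotransmitter secretion",
    "synapse assembly",
    "neural crest cell migration",
    "positive regulation of neuronal apoptosis",
    "axonogenesis",
    "postsynaptic membrane organization",
)

#: GO term names guaranteed to contain none of the neural patterns.
_OTHER_TERM_NAMES = (
    "cell cycle arrest",
    "lipid metabolic process",
    "dna repair",
    "mitochondrial transport",
    "ribosome biogenesis",
    "protein folding",
    "regulation of glycolysis",
    "apoptotic signaling pathway",
    "cytoskeleton organization",
    "ion homeostasis",
    "rna splicing",
    "golgi vesicle transport",
    "chromatin remodeling",
    "response to oxidative stress",
    "cell adhesion",
    "translation initiation",
    "protein ubiquitination",
    "carbohydrate catabolic process",
    "angiogenesis regulation",
    "immune response activation",
)


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery checks.

    All fields are known exactly by construction; ``purity`` maps tumor
    sample ids to their simulated tumor-cell fraction.
    """

    neural_genes: frozenset[str] = frozenset()
    bivalent_genes: frozenset[str] = frozenset()
    hyper_genes: frozenset[str] = frozenset()
    hypo_genes: frozenset[str] = frozenset()
    diff_assoc_genes: frozenset[str] = frozenset()
    effect_m: float = 0.0
    neural_enrichment: float | None = None
    purity: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "neural_genes": sorted(self.neural_genes),
            "bivalent_genes": sorted(self.bivalent_genes),
            "hyper_genes": sorted(self.hyper_genes),
            "hypo_genes": sorted(self.hypo_genes),
            "diff_assoc_genes": sorted(self.diff_assoc_genes),
            "effect_m": self.effect_m,
            "neural_enrichment": self.neural_enrichment,
            "purity": self.purity,
            "seed": self.seed,
            "rng": "numpy PCG64",
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            neural_genes=frozenset(raw["neural_genes"]),
            bivalent_genes=frozenset(raw["bivalent_genes"]),
            hyper_genes=frozenset(raw["hyper_genes"]),
            hypo_genes=frozenset(raw["hypo_genes"]),
            diff_assoc_genes=frozenset(raw["diff_assoc_genes"]),
            effect_m=raw["effect_m"],
            neural_enrichment=raw["neural_enrichment"],
            purity=raw["purity"],
            seed=raw["seed"],
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def generate_universe(
    n_genes: int,
    probes_per_gene: int = 2,
    neural_fraction: float = 0.2,
    bivalent_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[ProbeAnnotation, GoAnnotation, GeneSetCollection, SyntheticTruth]:
    """Build a gene/probe/GO universe with known neural and bivalent labels.

    Every gene receives one promoter probe (label drawn from TSS200 /
    TSS1500 / 1stExon) plus ``probes_per_gene − 1`` further probes that are
    promoter or gene-body at random; island flags are independent
    Bernoulli(0.5). Neural genes get ≥1 GO term whose name contains a
    neural pattern; all other genes only pattern-free names, so the string
    classifier must flag exactly the planted set.
    """
    if n_genes < 10:
        raise ValidationError("need n_genes ≥ 10")
    if not (0 <= neural_fraction <= 1 and 0 <= bivalent_fraction <= 1):
        raise ValidationError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)

    n_neural = int(round(neural_fraction * n_genes))
    neural = frozenset(rng.choice(genes, size=n_neural, replace=False)) if n_neural else frozenset()
    n_biv = int(round(bivalent_fraction * n_genes))
    bivalent = frozenset(rng.choice(genes, size=n_biv, replace=False)) if n_biv else frozenset()

    promoter_labels = np.array(["TSS200", "TSS1500", "1stExon"])
    pair_rows: list[tuple[str, str, str]] = []
    island: dict[str, bool] = {}
    probe_no = 0
    for g in genes:
        for j in range(max(probes_per_gene, 1)):
            probe_no += 1
            pid = f"cg{probe_no:08d}"
            if j == 0:
                label = promoter_labels[rng.integers(3)]
            else:
                label = promoter_labels[rng.integers(3)] if rng.random() < 0.5 else "Body"
            pair_rows.append((pid, g, label))
            island[pid] = bool(rng.random() < 0.5)
    annotation = ProbeAnnotation(
        pairs=pd.DataFrame(pair_rows, columns=["probe_id", "gene_id", "region"]),
        island=pd.Series(island, name="island"),
    )

    # term pool: ids are stable per name; genes draw 1–3 terms
    neural_pool = [(f"GO:N{i:05d}", name) for i, name in enumerate(_NEURAL_TERM_NAMES)]
    other_pool = [(f"GO:O{i:05d}", name) for i, name in enumerate(_OTHER_TERM_NAMES)]
    go_rows: list[tuple[str, str, str, str]] = []
    for g in genes:
        if g in neural:
            k_neural = 1 + rng.integers(2)  # 1–2 neural terms
            picks = rng.choice(len(neural_pool), size=k_neural, replace=False)
            for i in picks:
                tid, name = neural_pool[i]
                go_rows.append((g, tid, name, "BP"))
            k_other = rng.integers(3)
        else:
            k_other = 1 + rng.integers(3)  # 1–3 non-neural terms
        picks = rng.choice(len(other_pool), size=int(k_other), replace=False)
        for i in picks:
            tid, name = other_pool[i]
            go_rows.append((g, tid, name, "BP"))
    go = GoAnnotation(
        records=pd.DataFrame(go_rows, columns=["gene_id", "term_id", "term_name", "namespace"])
    )

    sets = GeneSetCollection(sets={"bivalent": bivalent} if bivalent else {})
    truth = SyntheticTruth(neural_genes=neural, bivalent_genes=bivalent, seed=seed)
    return annotation, go, sets, truth


def choose_planted_genes(
    truth: SyntheticTruth,
    universe: list[str],
    n_hyper: int,
    neural_enrichment: float | None,
    rng: np.random.Generator,
    odds_sets: list[tuple[frozenset[str], float]] | None = None,
) -> frozenset[str]:
    """Pick planted hyper genes with a target neural share.

    ``neural_enrichment`` is the expected fraction of planted genes that
    are neural (None → the background neural rate, a null planting);
    ``odds_sets`` multiplies a gene's selection weight when it belongs to
    the given set (e.g. 3× odds for bivalent genes), applied within the
    neural and non-neural strata so the neural share stays on target.
    """
    universe = list(universe)
    neural = [g for g in universe if g in truth.neural_genes]
    other = [g for g in universe if g not in truth.neural_genes]
    if neural_enrichment is None:
        neural_enrichment = len(neural) / len(universe)
    n_neural_pick = int(round(neural_enrichment * n_hyper))
    n_other_pick = n_hyper - n_neural_pick
    if n_neural_pick > len(neural) or n_other_pick > len(other):
        raise ValidationError(
            f"cannot plant {n_hyper} genes at neural share {neural_enrichment}: "
            f"need {n_neural_pick} of {len(neural)} neural and "
            f"{n_other_pick} of {len(other)} non-neural genes"
        )

    def weighted_pick(pool: list[str], k: int) -> list[str]:
        if k == 0:
            return []
        w = np.ones(len(pool))
        for members, odds in odds_sets or []:
            w *= np.where([g in members for g in pool], odds, 1.0)
        return list(rng.choice(pool, size=k, replace=False, p=w / w.sum()))

    return frozenset(weighted_pick(neural, n_neural_pick) + weighted_pick(other, n_other_pick))


def _m_to_beta_pure(m: np.ndarray) -> np.ndarray:
    """Logistic back-transform; finite M never yields exactly 0 or 1."""
    return 1.0 / (1.0 + np.exp2(-m))


def generate_methylation(
    annotation: ProbeAnnotation,
    truth: SyntheticTruth,
    n_hyper: int,
    effect_m: float,
    n_normal: int = 20,
    n_tumor: int = 20,
    neural_enrichment: float | None = None,
    n_hypo: int = 0,
    purity_model: tuple[float, float] | None = None,
    odds_sets: list[tuple[frozenset[str], float]] | None = None,
    cancer_type: str = "SIM",
    seed: int = 0,
) -> tuple[MethylationDataset, SyntheticTruth]:
    """Simulate a two-group beta matrix with planted promoter shifts.

    Planted hyper genes have all their promoter probes shifted by
    ``+effect_m`` (M-scale) in the pure tumor signal; hypo genes mirrored.
    When ``purity_model=(a, b)``, each tumor sample's purity is drawn
    uniform on [a, b] and its observed beta is the purity-weighted mixture
    of pure-tumor and normal-contamination betas.
    """
    if n_normal < 3 or n_tumor < 3:
        raise ValidationError("need ≥3 samples per group")
    if effect_m < 0:
        raise ValidationError("effect_m must be ≥ 0")
    rng = np.random.default_rng(seed)
    genes = sorted(annotation.genes)

    hyper = choose_planted_genes(truth, genes, n_hyper, neural_enrichment, rng, odds_sets)
    hypo: frozenset[str] = frozenset()
    if n_hypo:
        remaining = [g for g in genes if g not in hyper]
        hypo = choose_planted_genes(truth, remaining, n_hypo, None, rng)

    probes = list(annotation.probe_ids)
    probe_index = {p: i for i, p in enumerate(probes)}
    n_probes = len(probes)

    # pure-tumor M shift per probe: promoter probes of planted genes only
    shift = np.zeros(n_probes)
    promoter = annotation.promoter_pairs()
    for pid, gid in promoter[["probe_id", "gene_id"]].itertuples(index=False):
        if gid in hyper:
            shift[probe_index[pid]] = effect_m
        elif gid in hypo:
            shift[probe_index[pid]] = -effect_m

    m0 = rng.normal(0.0, BASELINE_M_SD, size=n_probes)
    # promoters that gain methylation in cancer start from the unmethylated
    # mode (and mirrored for losses): the planted effect must be expressible
    # on the bounded beta scale, as it is biologically
    planted = shift != 0
    if planted.any():
        m0[planted] = rng.normal(
            -np.sign(shift[planted]) * PLANTED_BASELINE_M,
            PLANTED_BASELINE_SD,
            size=int(planted.sum()),
        )
    # scaled inverse-chi-squared probe variances: s0²·d0 / χ²_{d0}
    sigma_sq = NOISE_PRIOR_VAR * NOISE_PRIOR_DF / rng.chisquare(NOISE_PRIOR_DF, size=n_probes)
    sigma = np.sqrt(sigma_sq)

    normal_ids = [f"N{i:03d}" for i in range(1, n_normal + 1)]
    tumor_ids = [f"T{i:03d}" for i in range(1, n_tumor + 1)]
    if purity_model is None:
        purity = np.ones(n_tumor)
    else:
        a, b = purity_model
        if not (0 <= a <= b <= 1):
            raise ValidationError("purity bounds must satisfy 0 ≤ a ≤ b ≤ 1")
        purity = rng.uniform(a, b, size=n_tumor)

    noise = lambda cols: rng.normal(0.0, 1.0, size=(n_probes, cols)) * sigma[:, None]
    beta_normal = _m_to_beta_pure(m0[:, None] + noise(n_normal))
    beta_tumor_pure = _m_to_beta_pure((m0 + shift)[:, None] + noise(n_tumor))
    beta_contam = _m_to_beta_pure(m0[:, None] + noise(n_tumor))
    beta_tumor = purity[None, :] * beta_tumor_pure + (1.0 - purity[None, :]) * beta_contam

    beta = pd.DataFrame(
        np.hstack([beta_normal, beta_tumor]), index=probes, columns=normal_ids + tumor_ids
    )
    samples = pd.DataFrame(
        {
            "group": ["normal"] * n_normal + ["tumor"] * n_tumor,
            "cancer_type": cancer_type,
            "purity": [np.nan] * n_normal + list(purity),
            "age": np.round(rng.uniform(40, 80, size=n_normal + n_tumor), 1),
            "sex": rng.choice(["F", "M"], size=n_normal + n_tumor),
        },
        index=pd.Index(normal_ids + tumor_ids, name="sample_id"),
    )
    dataset = MethylationDataset(beta=beta, samples=samples)
    new_truth = SyntheticTruth(
        neural_genes=truth.neural_genes,
        bivalent_genes=truth.bivalent_genes,
        hyper_genes=hyper,
        hypo_genes=hypo,
        diff_assoc_genes=truth.diff_assoc_genes,
        effect_m=effect_m,
        neural_enrichment=neural_enrichment,
        purity={s: float(p) for s, p in zip(tumor_ids, purity)},
        seed=seed,
    )
    return dataset, new_truth


def generate_hallmark_sets(
    genes: list[str] | frozenset[str],
    n_sets: int = 10,
    set_size: int = 200,
    seed: int = 0,
) -> GeneSetCollection:
    """Random hallmark-style gene sets drawn from the universe."""
    rng = np.random.default_rng(seed)
    genes = sorted(genes)
    if set_size > len(genes):
        raise ValidationError("set_size exceeds universe size")
    sets = {
        f"hallmark_{i:02d}": frozenset(rng.choice(genes, size=set_size, replace=False))
        for i in range(1, n_sets + 1)
    }
    return GeneSetCollection(sets=sets)


def generate_expression(
    genes: list[str] | frozenset[str],
    diff_assoc: frozenset[str] | set[str],
    n_per_condition: int = 10,
    shift: float = 2.0,
    age_effect: float = 0.05,
    sex_effect: float = 1.0,
    covariate_gene_fraction: float = 0.1,
    confound_age_with_condition: bool = False,
    conditions: tuple[str, str] = ("progenitor", "neuron"),
    seed: int = 0,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate a log-scale expression matrix with a differentiation contrast.

    ``diff_assoc`` genes are shifted by ``+shift`` (log2) in the second
    condition relative to the first (default neuron vs progenitor; pass
    negative ``shift`` to plant downregulation). A random ``covariate_gene_fraction``
    of genes carries an additive age slope (``age_effect`` per year) and
    another a sex offset, so covariate adjustment is genuinely exercised;
    with ``confound_age_with_condition`` the neuron samples are drawn older,
    making the age signal masquerade as differential expression unless
    adjusted for.
    """
    genes = sorted(genes)
    diff_assoc = frozenset(diff_assoc)
    if not diff_assoc <= set(genes):
        raise ValidationError("diff_assoc must be a subset of the gene universe")
    if n_per_condition < 3:
        raise ValidationError("need ≥3 samples per condition")
    rng = np.random.default_rng(seed)
    n_genes = len(genes)

    baseline = rng.normal(6.0, 1.5, size=n_genes)
    sigma = np.sqrt(NOISE_PRIOR_VAR * NOISE_PRIOR_DF / rng.chisquare(NOISE_PRIOR_DF, size=n_genes))

    n_cov = int(round(covariate_gene_fraction * n_genes))
    age_genes = frozenset(rng.choice(genes, size=n_cov, replace=False)) if n_cov else frozenset()
    sex_genes = frozenset(rng.choice(genes, size=n_cov, replace=False)) if n_cov else frozenset()

    prog_ids = [f"{conditions[0][0].upper()}E{i:03d}" for i in range(1, n_per_condition + 1)]
    neur_ids = [f"{conditions[1][0].upper()}X{i:03d}" for i in range(1, n_per_condition + 1)]
    condition = np.array([0] * n_per_condition + [1] * n_per_condition)
    if confound_age_with_condition:
        age = np.concatenate(
            [rng.uniform(25, 45, n_per_condition), rng.uniform(45, 65, n_per_condition)]
        )
    else:
        age = rng.uniform(25, 65, size=2 * n_per_condition)
    sex = rng.choice([0, 1], size=2 * n_per_condition)

    in_diff = np.array([g in diff_assoc for g in genes], dtype=float)
    in_age = np.array([g in age_genes for g in genes], dtype=float)
    in_sex = np.array([g in sex_genes for g in genes], dtype=float)

    mu = (
        baseline[:, None]
        + shift * in_diff[:, None] * condition[None, :]
        + age_effect * in_age[:, None] * (age - age.mean())[None, :]
        + sex_effect * in_sex[:, None] * sex[None, :]
    )
    values = mu + rng.normal(0.0, 1.0, size=mu.shape) * sigma[:, None]

    expr = pd.DataFrame(values, index=genes, columns=prog_ids + neur_ids)
    samples = pd.DataFrame(
        {
            "condition": [conditions[0]] * n_per_condition + [conditions[1]] * n_per_condition,
            "age": np.round(age, 1),
            "sex": np.where(sex == 1, "M", "F"),
        },
        index=pd.Index(prog_ids + neur_ids, name="sample_id"),
    )
    dataset = ExpressionDataset(log_expr=expr, samples=samples, is_counts=False)
    truth = SyntheticTruth(diff_assoc_genes=diff_assoc, seed=seed)
    return dataset, truth
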