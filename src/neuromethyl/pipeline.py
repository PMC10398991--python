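"""End-to-end orchestration: simulate → call → classify → test → report.

The pipeline runs on synthetic data with planted truth (or on user-supplied
tables via the stage CLIs), writing one TSV per stage plus a Table-1-style
enrichment summary across simulated cancer types, truth-recovery metrics,
and a MANIFEST. All randomness flows from a single seed; a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neuromethyl import annotation as ann
from neuromethyl import confounders, enrichment, expression, io, synthetic
from neuromethyl.datamodel import ValidationError
from neuromethyl.diffmeth import aggregate_genes, diff_methylation

STAGES = ("simulate", "diffmeth", "annotate", "enrich", "confound", "diffexpr", "overlap")


@dataclass
class RunConfig:
    """Pipeline configuration; CLI flags override file values."""

    outdir: str = "neuromethyl_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # universe
    n_genes: int = 2000
    probes_per_gene: int = 2
    neural_fraction: float = 0.186
    bivalent_fraction: float = 0.1
    # methylation simulation
    cancer_types: tuple[str, ...] = ("SIM1", "SIM2")
    n_hyper: int = 300
    n_hypo: int = 150
    effect_m: float = 3.0
    neural_enrichment: float = 0.385
    n_normal: int = 12
    n_tumor: int = 12
    purity_uniform: tuple[float, float] | None = (0.4, 0.95)
    # calling thresholds
    alpha: float = 0.05
    lfc: float = 1.0
    dbeta: float = 0.1
    island_only: bool = False
    patterns: tuple[str, ...] = ann.NEURAL_PATTERNS
    # expression simulation
    n_diff_assoc: int = 150
    expr_shift: float = 2.0
    n_per_condition: int = 10
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stage names: {sorted(unknown)}")
        if self.alpha <= 0 or self.lfc <= 0 or self.dbeta <= 0:
            raise ValidationError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("stages", "cancer_types", "patterns"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("purity_uniform") is not None and "purity_uniform" in kwargs:
            kwargs["purity_uniform"] = tuple(kwargs["purity_uniform"])
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs)
        if cfg.extra:
            raise ValidationError(f"unknown config keys: {sorted(cfg.extra)}")
        return cfg


def export_ipa(probe_table: pd.DataFrame, path) -> None:
    """Export called loci for external upstream-regulator tools.

    Promoter DNA methylation is treated as a silencing mark, so
    hypermethylated loci are exported with direction "down" (in place of
    downregulated genes) and hypomethylated loci with direction "up".
    """
    called = probe_table[probe_table["call"] != "ns"]
    out = pd.DataFrame(
        {
            "probe_id": called.index,
            "logFC_m": called["logFC_m"],
            "p_adj": called["p_adj"],
            "direction": np.where(called["call"] == "hyper", "down", "up"),
        }
    ).set_index("probe_id")
    io.write_table(out, path, index_label="probe_id")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns a results dict keyed by stage.

    Outputs land under ``config.outdir``; any stage failure aborts with the
    failing stage named, leaving partial outputs and a MANIFEST that
    records the incompleteness.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    results: dict = {}

    def emit(name: str, writer) -> None:
        writer(outdir / name)
        manifest.append(name)

    def finish_manifest(status: str) -> None:
        (outdir / "MANIFEST").write_text(
            "\n".join([f"# status: {status}"] + sorted(manifest)) + "\n"
        )

    current = "simulate"
    try:
        io.write_run_metadata(
            outdir / "run_metadata.json",
            seed=config.seed,
            alpha=config.alpha,
            lfc=config.lfc,
            dbeta=config.dbeta,
            island_only=config.island_only,
            patterns=list(config.patterns),
            stages=list(config.stages),
            n_genes=config.n_genes,
            cancer_types=list(config.cancer_types),
        )
        manifest.append("run_metadata.json")

        # --- simulate ----------------------------------------------------
        annotation, go, gene_sets, truth0 = synthetic.generate_universe(
            n_genes=config.n_genes,
            probes_per_gene=config.probes_per_gene,
            neural_fraction=config.neural_fraction,
            bivalent_fraction=config.bivalent_fraction,
            seed=config.seed,
        )
        genes = sorted(annotation.genes)
        if "simulate" in config.stages:
            emit("probe_annotation.tsv", lambda p: io.write_probe_annotation(annotation, p))
            emit("go_annotation.tsv", lambda p: io.write_go_annotation(go, p))
            if len(gene_sets):
                emit("gene_sets.gmt", lambda p: io.write_gene_sets(gene_sets, p))
        results["universe"] = (annotation, go, gene_sets, truth0)

        datasets = {}
        truths = {}
        for i, ct in enumerate(config.cancer_types):
            ds, tr = synthetic.generate_methylation(
                annotation,
                truth0,
                n_hyper=config.n_hyper,
                n_hypo=config.n_hypo,
                effect_m=config.effect_m,
                neural_enrichment=config.neural_enrichment,
                n_normal=config.n_normal,
                n_tumor=config.n_tumor,
                purity_model=config.purity_uniform,
                cancer_type=ct,
                seed=config.seed + 1000 + i,
            )
            datasets[ct], truths[ct] = ds, tr
            if "simulate" in config.stages:
                emit(f"beta_{ct}.tsv", lambda p, ds=ds: io.write_methylation(ds, p, str(p).replace("beta_", "samples_")))
                manifest.append(f"samples_{ct}.tsv")
                emit(f"truth_{ct}.json", lambda p, tr=tr: tr.to_json(p))
        results["datasets"] = datasets
        results["truths"] = truths

        # --- diffmeth ----------------------------------------------------
        current = "diffmeth"
        calls_by_ct = {}
        tables_by_ct = {}
        if "diffmeth" in config.stages:
            for ct, ds in datasets.items():
                table, _ = diff_methylation(
                    ds, alpha=config.alpha, lfc=config.lfc, dbeta=config.dbeta
                )
                gene_calls = aggregate_genes(table, annotation, island_only=config.island_only)
                tables_by_ct[ct] = table
                calls_by_ct[ct] = gene_calls
                emit(f"diffmeth_probes_{ct}.tsv", lambda p, t=table: io.write_table(t, p, "probe_id"))
                gene_df = pd.DataFrame(
                    {
                        "gene_id": sorted(gene_calls.tested_genes),
                    }
                ).set_index("gene_id")
                gene_df["hyper"] = [g in gene_calls.hyper_genes for g in gene_df.index]
                gene_df["hypo"] = [g in gene_calls.hypo_genes for g in gene_df.index]
                emit(f"gene_calls_{ct}.tsv", lambda p, d=gene_df: io.write_table(d, p, "gene_id"))
            results["calls"] = calls_by_ct
            results["probe_tables"] = tables_by_ct

        # --- annotate ----------------------------------------------------
        current = "annotate"
        flags = ann.classify(go, config.patterns)
        if "annotate" in config.stages:
            flag_df = pd.DataFrame(
                {
                    "gene_id": sorted(flags.flags),
                }
            ).set_index("gene_id")
            flag_df["neural"] = [flags[g] for g in flag_df.index]
            flag_df["witness_terms"] = [
                ";".join(sorted({t for t, _ in flags.matched_terms.get(g, set())}))
                for g in flag_df.index
            ]
            emit("neural_flags.tsv", lambda p: io.write_table(flag_df, p, "gene_id"))
        results["flags"] = flags

        # --- enrich ------------------------------------------------------
        current = "enrich"
        if "enrich" in config.stages and calls_by_ct:
            rows = []
            for ct, gene_calls in calls_by_ct.items():
                rows.append(enrichment.neural_enrichment_test(gene_calls, flags, "hyper", ct))
                if gene_calls.hypo_genes:
                    rows.append(enrichment.neural_enrichment_test(gene_calls, flags, "hypo", ct))
            summary = enrichment.fdr_across_cancers(rows)
            emit("enrichment_summary.tsv", lambda p: io.write_table(summary, p))
            results["enrichment"] = summary
            hyper_pct = summary.loc[summary["direction"] == "hyper", "pct_neural"]
            hypo_pct = summary.loc[summary["direction"] == "hypo", "pct_neural"]
            if len(hyper_pct) >= 3 and len(hyper_pct) == len(hypo_pct):
                t, df, p = enrichment.paired_t_test(hyper_pct.to_numpy(), hypo_pct.to_numpy())
                results["paired_t"] = {"t": t, "df": df, "p": p}

        # --- confound ----------------------------------------------------
        current = "confound"
        if "confound" in config.stages and calls_by_ct:
            ct0 = config.cancer_types[0]
            ds, gene_calls = datasets[ct0], calls_by_ct[ct0]
            if config.purity_uniform is not None:
                purity_df = confounders.purity_regression(ds, gene_calls, flags, annotation)
                emit("purity_regression.tsv", lambda p: io.write_table(purity_df, p))
                results["purity"] = purity_df
            degree = confounders.methylation_degree_compare(ds, gene_calls, flags, annotation)
            (outdir / "methylation_degree.json").write_text(json.dumps(degree, indent=2) + "\n")
            manifest.append("methylation_degree.json")
            results["degree"] = degree
            if "bivalent" in gene_sets.sets:
                biv = confounders.bivalency_crosstab(
                    gene_calls, flags, gene_sets["bivalent"], gene_calls.tested_genes
                )
                emit("bivalency_crosstab.tsv", lambda p: io.write_table(biv, p))
                results["bivalency"] = biv
            hallmarks = synthetic.generate_hallmark_sets(
                genes, n_sets=10, set_size=max(20, config.n_genes // 10), seed=config.seed + 7
            )
            hm = confounders.hallmark_enrichment(gene_calls, flags, hallmarks)
            emit("hallmark_enrichment.tsv", lambda p: io.write_table(hm, p))
            results["hallmarks"] = hm

        # --- diffexpr ----------------------------------------------------
        current = "diffexpr"
        diff_assoc_set = frozenset()
        if "diffexpr" in config.stages:
            rng = np.random.default_rng(config.seed + 2000)
            # couple the planted differentiation set to planted hyper genes of
            # the first cancer type so the overlap stage has signal to find
            planted_hyper = sorted(truths[config.cancer_types[0]].hyper_genes)
            n_from_hyper = min(len(planted_hyper), config.n_diff_assoc // 2)
            rest_pool = [g for g in genes if g not in set(planted_hyper)]
            diff_assoc_set = frozenset(
                list(rng.choice(planted_hyper, size=n_from_hyper, replace=False))
                + list(rng.choice(rest_pool, size=config.n_diff_assoc - n_from_hyper, replace=False))
            )
            expr_ds, expr_truth = synthetic.generate_expression(
                genes,
                diff_assoc_set,
                n_per_condition=config.n_per_condition,
                shift=config.expr_shift,
                seed=config.seed + 2001,
            )
            de = expression.de_expression(
                expr_ds, contrast=("neuron", "progenitor"), covariates=("age", "sex")
            )
            emit("differentiation_de.tsv", lambda p: io.write_table(de, p, "gene_id"))
            results["diff_de"] = de
            results["diff_assoc"] = expression.classify_differentiation(de)
            results["diff_truth"] = expr_truth

        # --- overlap -----------------------------------------------------
        current = "overlap"
        if "overlap" in config.stages and calls_by_ct and "diff_assoc" in results:
            ct0 = config.cancer_types[0]
            gene_calls = calls_by_ct[ct0]
            # cancer expression contrast: planted downregulation on a subset
            # of hypermethylated genes (promoter methylation silences)
            rng = np.random.default_rng(config.seed + 3000)
            hyper_genes = sorted(truths[ct0].hyper_genes)
            n_dr = max(len(hyper_genes) // 3, 1)
            dr_planted = frozenset(rng.choice(hyper_genes, size=n_dr, replace=False))
            cancer_expr, _ = synthetic.generate_expression(
                genes,
                dr_planted,
                n_per_condition=config.n_per_condition,
                shift=-config.expr_shift,
                conditions=("normal", "tumor"),
                seed=config.seed + 3001,
            )
            de_cancer = expression.de_expression(
                cancer_expr, contrast=("tumor", "normal"), covariates=()
            )
            report = expression.overlap_stats(
                gene_calls, results["diff_assoc"], flags, de_cancer
            )
            emit("overlap_shares.tsv", lambda p: io.write_table(report.shares, p))
            if not report.expression_composition.empty:
                emit(
                    "overlap_expression.tsv",
                    lambda p: io.write_table(report.expression_composition, p),
                )
            results["overlap"] = report
            emit("ipa_export.tsv", lambda p: export_ipa(tables_by_ct[ct0], p))

        # --- recovery metrics ---------------------------------------------
        if calls_by_ct:
            recov = {}
            for ct, gene_calls in calls_by_ct.items():
                tr = truths[ct]
                called = gene_calls.hyper_genes
                planted = tr.hyper_genes
                neural = flags.flagged()
                recov[ct] = {
                    "sensitivity_hyper": len(called & planted) / len(planted) if planted else np.nan,
                    "n_called_hyper": len(called),
                    "neural_share_called_pct": 100 * len(called & neural) / len(called) if called else np.nan,
                    "neural_share_planted_pct": 100 * len(planted & neural) / len(planted) if planted else np.nan,
                    "background_neural_pct": 100
                    * len(gene_calls.tested_genes & neural)
                    / len(gene_calls.tested_genes),
                }
            (outdir / "recovery.json").write_text(json.dumps(recov, indent=2) + "\n")
            manifest.append("recovery.json")
            results["recovery"] = recov
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        finish_manifest(f"FAILED at stage {current}: {exc}")
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc
    finish_manifest("complete")
    return results
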