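"""Readers and writers for the package's tabular formats.

Matrices, sample sheets and annotation tables are tab-delimited UTF-8 with a
header row; gene sets use GMT. Annotation list fields (multiple genes per
probe) are semicolon-delimited, mirroring Illumina manifest conventions.
Output tables are written with deterministic (key-sorted) row order.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from neuromethyl.datamodel import (
    ExpressionDataset,
    GeneSetCollection,
    GoAnnotation,
    MethylationDataset,
    ProbeAnnotation,
    ValidationError,
)

#: significant digits used when writing float columns
FLOAT_FORMAT = "%.12g"


def read_methylation(beta_path, samplesheet_path) -> MethylationDataset:
    """Read a beta matrix TSV (probes × samples) and its sample sheet."""
    beta = pd.read_csv(beta_path, sep="\t", index_col=0)
    samples = pd.read_csv(samplesheet_path, sep="\t", index_col=0, dtype={0: str})
    samples.index = samples.index.astype(str)
    beta.columns = beta.columns.astype(str)
    return MethylationDataset(beta=beta, samples=samples)


def write_methylation(dataset: MethylationDataset, beta_path, samplesheet_path) -> None:
    dataset.beta.to_csv(beta_path, sep="\t", float_format=FLOAT_FORMAT, index_label="probe_id")
    dataset.samples.to_csv(samplesheet_path, sep="\t", index_label="sample_id")


def read_probe_annotation(path) -> ProbeAnnotation:
    """Parse a probe annotation TSV.

    Expected columns: ``probe_id``, ``gene_ids`` (semicolon-joined),
    ``region_labels`` (semicolon-joined, aligned with gene_ids) and
    ``island_flag`` (0/1). A row with empty ``gene_ids`` keeps the probe
    (island flag recorded) but maps it to no gene.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"probe_id", "gene_ids", "region_labels", "island_flag"}
    if not needed.issubset(raw.columns):
        raise ValidationError(f"annotation file needs columns {sorted(needed)}")
    rows = []
    island = {}
    for rec in raw.itertuples(index=False):
        probe = rec.probe_id
        island[probe] = str(rec.island_flag).strip().lower() in {"1", "true", "yes"}
        genes = [g for g in rec.gene_ids.split(";") if g]
        labels = [r for r in rec.region_labels.split(";") if r]
        if not genes:
            continue
        if len(genes) != len(labels):
            raise ValidationError(
                f"probe {probe!r}: {len(genes)} gene ids but {len(labels)} region labels"
            )
        for g, r in zip(genes, labels):
            rows.append((probe, g, r))
    pairs = pd.DataFrame(rows, columns=["probe_id", "gene_id", "region"])
    return ProbeAnnotation(pairs=pairs, island=pd.Series(island, name="island"))


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    grouped = annotation.pairs.groupby("probe_id", sort=True)
    lines = ["probe_id\tgene_ids\tregion_labels\tisland_flag"]
    seen = set()
    for probe, grp in grouped:
        grp = grp.sort_values("gene_id")
        lines.append(
            f"{probe}\t{';'.join(grp['gene_id'])}\t{';'.join(grp['region'])}"
            f"\t{int(annotation.island.get(probe, False))}"
        )
        seen.add(probe)
    for probe in sorted(set(annotation.island.index) - seen):
        lines.append(f"{probe}\t\t\t{int(annotation.island[probe])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_go_annotation(path) -> GoAnnotation:
    records = pd.read_csv(path, sep="\t", dtype=str)
    return GoAnnotation(records=records)


def write_go_annotation(go: GoAnnotation, path) -> None:
    go.records.sort_values(["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"GMT line {lineno}: fewer than 3 fields")
        name = fields[0]
        if name in sets:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        members = frozenset(g for g in fields[2:] if g)
        if not members:
            raise ValidationError(f"GMT line {lineno}: set {name!r} has no members")
        sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path, description: str = "na") -> None:
    lines = [
        f"{name}\t{description}\t" + "\t".join(sorted(members))
        for name, members in sorted(collection.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(expr_path, samplesheet_path, is_counts: bool = False) -> ExpressionDataset:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = pd.read_csv(samplesheet_path, sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return ExpressionDataset(log_expr=expr, samples=samples, is_counts=is_counts)


def write_expression(dataset: ExpressionDataset, expr_path, samplesheet_path) -> None:
    dataset.log_expr.to_csv(expr_path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")
    dataset.samples.to_csv(samplesheet_path, sep="\t", index_label="sample_id")


def write_table(table: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Write a result table as TSV with header and key-sorted rows."""
    out = table.sort_index()
    out.to_csv(
        path,
        sep="\t",
        float_format=FLOAT_FORMAT,
        index=index_label is not None,
        index_label=index_label,
    )


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_run_metadata(path, **fields) -> None:
    """Record run parameters (thresholds, seed, versions) as JSON."""
    import neuromethyl

    meta = {"package_version": neuromethyl.__version__, "rng": "numpy PCG64"}
    meta.update(fields)
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
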