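"""Domain types for methylation, annotation and expression data.

All tabular containers wrap pandas objects; validation happens at
construction so downstream stages can assume consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = {"normal", "tumor", "premalignant"}

#: Region labels an annotation table may carry per (probe, gene) pair.
REGION_VOCABULARY = {"TSS200", "TSS1500", "1stExon", "5'UTR", "Body", "3'UTR"}

#: Labels that define a promoter probe for gene aggregation.
PROMOTER_LABELS = frozenset({"TSS200", "TSS1500", "1stExon"})


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


@dataclass
class MethylationDataset:
    """Beta-value matrix (probes × samples) plus its sample sheet.

    Parameters
    ----------
    beta
        DataFrame of methylation fractions in [0, 1], indexed by probe id,
        one column per sample. Missing entries stay as NaN.
    samples
        Sample sheet indexed by sample_id with columns ``group``
        (normal/tumor/premalignant), ``cancer_type``, and optional
        ``purity`` (fraction), ``age`` (years), ``sex``.
    """

    beta: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.samples.index.has_duplicates:
            dups = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dups}")
        if self.beta.index.has_duplicates:
            dups = self.beta.index[self.beta.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe ids: {dups}")
        missing = [s for s in self.beta.columns if s not in self.samples.index]
        if missing:
            raise ValidationError(
                f"beta matrix columns without a sample-sheet row: {missing}"
            )
        if "group" not in self.samples.columns:
            raise ValidationError("sample sheet lacks a 'group' column")
        bad_groups = set(self.samples["group"].dropna()) - VALID_GROUPS
        if bad_groups:
            raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out = (vals < 0) | (vals > 1)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ValidationError(
                "beta value outside [0,1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}: "
                f"{vals[i, j]}"
            )
        # keep only sheet rows for samples that are actually in the matrix
        self.samples = self.samples.loc[list(self.beta.columns)]

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    def group_samples(self, group: str) -> list[str]:
        return self.samples.index[self.samples["group"] == group].tolist()

    def subset_samples(self, sample_ids: list[str]) -> "MethylationDataset":
        return MethylationDataset(
            beta=self.beta[sample_ids].copy(), samples=self.samples.loc[sample_ids].copy()
        )


@dataclass
class ProbeAnnotation:
    """Probe→gene mapping with per-pair region labels and per-probe island flag.

    ``pairs`` holds one row per (probe, gene) association with columns
    ``probe_id``, ``gene_id``, ``region`` (single label from
    :data:`REGION_VOCABULARY`); a probe mapping to no gene simply has no
    rows. ``island`` maps probe_id → bool (CpG-island membership).
    """

    pairs: pd.DataFrame
    island: pd.Series

    def __post_init__(self) -> None:
        needed = {"probe_id", "gene_id", "region"}
        if not needed.issubset(self.pairs.columns):
            raise ValidationError(f"pair table needs columns {sorted(needed)}")
        bad = set(self.pairs["region"]) - REGION_VOCABULARY
        if bad:
            raise ValidationError(f"unknown region labels: {sorted(bad)}")
        if self.island.index.has_duplicates:
            raise ValidationError("duplicate probe ids in island flag")

    @property
    def probe_ids(self) -> pd.Index:
        return self.island.index

    @property
    def genes(self) -> set[str]:
        return set(self.pairs["gene_id"].unique())

    def promoter_pairs(
        self,
        promoter_labels: frozenset[str] = PROMOTER_LABELS,
        island_only: bool = False,
    ) -> pd.DataFrame:
        """(probe, gene) pairs whose region label marks a promoter probe."""
        sel = self.pairs[self.pairs["region"].isin(promoter_labels)]
        if island_only:
            on_island = self.island.reindex(sel["probe_id"]).fillna(False).to_numpy(bool)
            sel = sel[on_island]
        return sel.drop_duplicates(subset=["probe_id", "gene_id"])


@dataclass
class GoAnnotation:
    """Gene→GO-term records: gene_id, term_id, term_name, namespace."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"gene_id", "term_id", "term_name"}
        if not needed.issubset(self.records.columns):
            raise ValidationError(f"GO table needs columns {sorted(needed)}")
        if "namespace" not in self.records.columns:
            self.records = self.records.assign(namespace="BP")
        if (self.records["term_name"].astype(str).str.len() == 0).any():
            raise ValidationError("empty term_name in GO annotation")
        dup = self.records.duplicated(subset=["gene_id", "term_id"])
        if dup.any():
            pair = self.records.loc[dup.idxmax(), ["gene_id", "term_id"]].tolist()
            raise ValidationError(f"duplicate (gene_id, term_id) pair: {pair}")

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene_id"].unique())

    def terms(self) -> pd.DataFrame:
        """Unique (term_id, term_name) rows."""
        return self.records[["term_id", "term_name"]].drop_duplicates("term_id")


@dataclass
class GeneSetCollection:
    """Named gene sets (bivalent set, cancer-hallmark sets, user sets)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = frozenset(members)
        self.sets = clean

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class ExpressionDataset:
    """Log-scale expression matrix (genes × samples) plus a sample sheet.

    ``is_counts`` marks matrices of log-scaled counts whose mean–variance
    relationship warrants precision weights in differential testing.
    """

    log_expr: pd.DataFrame
    samples: pd.DataFrame
    is_counts: bool = False

    def __post_init__(self) -> None:
        if self.log_expr.index.has_duplicates:
            dups = self.log_expr.index[self.log_expr.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if "condition" not in self.samples.columns:
            raise ValidationError("expression sample sheet lacks 'condition'")
        missing = [s for s in self.log_expr.columns if s not in self.samples.index]
        if missing:
            raise ValidationError(f"expression columns without sheet row: {missing}")
        if self.samples.loc[list(self.log_expr.columns), "condition"].nunique() < 2:
            raise ValidationError("condition needs at least 2 levels")
        self.samples = self.samples.loc[list(self.log_expr.columns)]
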