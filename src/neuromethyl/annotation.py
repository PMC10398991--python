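"""Neural-related gene classification by GO term-name string matching.

A GO term is neural-related when its lower-cased name contains at least one
of the configured pattern strings as a substring; a gene is neural-related
when it is annotated to at least one such term. Substring (not word-boundary)
semantics are deliberate — "neuro" must match "neurotransmitter" — at the
cost of occasional false matches such as "dendritic cell" (immune).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from neuromethyl.datamodel import GoAnnotation, ValidationError

#: Default neural pattern strings matched against GO term names.
NEURAL_PATTERNS: tuple[str, ...] = (
    "neuro",
    "neuron",
    "neuronal",
    "neural",
    "nervous",
    "axon",
    "dendritic",
    "synaptic",
    "synapse",
    "learning",
    "memory",
    "brain",
    "hippocampus",
)


@dataclass
class NeuralFlags:
    """Per-gene neural-related flags with matching-term witnesses.

    ``matched_terms`` maps each flagged gene to the set of
    (term_id, pattern) pairs that justify the flag.
    """

    flags: dict[str, bool]
    matched_terms: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> bool:
        return self.flags.get(gene_id, False)

    def flagged(self) -> frozenset[str]:
        return frozenset(g for g, f in self.flags.items() if f)


def neural_terms(
    go: GoAnnotation, patterns: tuple[str, ...] = NEURAL_PATTERNS
) -> dict[str, set[str]]:
    """Flag GO terms whose name contains any pattern (case-insensitive).

    Returns
    -------
    dict
        term_id → set of patterns found in the term's name. Only flagged
        terms appear as keys.
    """
    if not patterns:
        raise ValidationError("pattern list must be non-empty")
    lowered = [p.lower() for p in patterns]
    hits: dict[str, set[str]] = {}
    for term_id, name in go.terms().itertuples(index=False):
        lname = str(name).lower()
        found = {p for p in lowered if p in lname}
        if found:
            hits[term_id] = found
    return hits


def flag_genes(go: GoAnnotation, neural_term_hits: dict[str, set[str]]) -> NeuralFlags:
    """Flag genes annotated to at least one neural-related term.

    Genes with no GO records are absent from ``flags`` and treated as
    unflagged by lookup.
    """
    flags: dict[str, bool] = {}
    witnesses: dict[str, set[tuple[str, str]]] = {}
    for gene_id, term_id in go.records[["gene_id", "term_id"]].itertuples(index=False):
        flags.setdefault(gene_id, False)
        pats = neural_term_hits.get(term_id)
        if pats:
            flags[gene_id] = True
            witnesses.setdefault(gene_id, set()).update((term_id, p) for p in sorted(pats))
    return NeuralFlags(flags=flags, matched_terms=witnesses)


def classify(go: GoAnnotation, patterns: tuple[str, ...] = NEURAL_PATTERNS) -> NeuralFlags:
    """Convenience wrapper: term matching then gene flagging."""
    return flag_genes(go, neural_terms(go, patterns))


def background_fraction(flags: NeuralFlags, universe: set[str] | frozenset[str]) -> float:
    """Fraction of a gene universe flagged neural-related."""
    if not universe:
        raise ValidationError("empty gene universe")
    flagged = flags.flagged()
    return len(flagged & frozenset(universe)) / len(universe)
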