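"""Functional-annotation bookkeeping: domain-hit filtering and GO joining.

Protein-domain hits (hmmscan against Pfam) are filtered at an E-value
threshold (default 1e-05, inclusive), then joined to Gene Ontology
terms through a flat Pfam→GO mapping. Each kept hit contributes one
annotation instance per GO term its domain maps to; instances are
tallied per ontology root (molecular function, biological process,
cellular component).
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import DomainHit, GoAnnotation, GO_CLASSES


@dataclass(frozen=True)
class DomainSummary:
    n_hits: int
    n_unique_domains: int
    n_unique_genes: int


def filter_domain_hits(
    hits: list[DomainHit], evalue_max: float = 1e-05
) -> tuple[list[DomainHit], DomainSummary]:
    """Keep hits with E <= ``evalue_max`` and summarize the kept cohort."""
    kept = [h for h in hits if h.evalue <= evalue_max]
    return kept, DomainSummary(
        n_hits=len(kept),
        n_unique_domains=len({h.domain_accession for h in kept}),
        n_unique_genes=len({h.query_id for h in kept}),
    )


def join_pfam_go(
    kept_hits: list[DomainHit],
    pfam2go_map: dict[str, list[tuple[str, str]]],
) -> tuple[list[GoAnnotation], dict[str, int]]:
    """Join kept domain hits to GO terms; tally instances per ontology class.

    One :class:`GoAnnotation` is emitted per (hit, mapped GO term);
    domains absent from the mapping contribute nothing. The tally dict
    always carries all three ontology roots (plus any other class
    labels present in the mapping).
    """
    annotations: list[GoAnnotation] = []
    tallies: dict[str, int] = {cls: 0 for cls in GO_CLASSES}
    for h in kept_hits:
        for go_id, go_class in pfam2go_map.get(h.domain_accession, []):
            annotations.append(
                GoAnnotation(
                    gene_id=h.query_id,
                    domain_accession=h.domain_accession,
                    go_id=go_id,
                    go_class=go_class,
                )
            )
            tallies[go_class] = tallies.get(go_class, 0) + 1
    return annotations, tallies
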