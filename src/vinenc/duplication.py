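"""Gene-duplication detection from a self-comparison hit table.

Given an all-by-all self comparison of one annotation's proteins and
the gene order along each chromosome, this module extracts duplicate
pairs, classifies them by genomic arrangement, and chains tandem pairs
into tandemly arrayed gene (TAG) arrays.

Classification is a simplified arrangement scheme on gene *rank* (order
index along the chromosome), not base-pair distance:

* ``tandem``    — same chromosome, adjacent ranks (|Δrank| = 1),
* ``proximal``  — same chromosome, 2 <= |Δrank| <= window (default 10),
* ``dispersed`` — everything else.

A gene's class is the highest-precedence kind among its pairs
(tandem > proximal > dispersed); genes with no duplicate pair are
singletons. Whole-genome/segmental duplication requires collinear-block
chaining and is out of scope. TAG arrays are the connected components
of the tandem-pair graph: a chain of adjacent pairs (g1,g2),(g2,g3)
forms one 3-gene array — equivalently, the second gene of each tandem
pair anchors the extension of the array.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import DataError
from .types import AlignmentHit, GeneModel

KIND_PRECEDENCE = ("tandem", "proximal", "dispersed")


@dataclass
class DuplicatePair:
    gene_1: str
    gene_2: str
    evalue: float
    bit_score: float
    kind: str | None = None

    def __post_init__(self):
        if self.gene_1 == self.gene_2:
            raise ValueError("a duplicate pair needs two distinct genes")
        if self.gene_1 > self.gene_2:
            self.gene_1, self.gene_2 = self.gene_2, self.gene_1


@dataclass(frozen=True)
class TandemArray:
    chromosome: str
    member_ids: tuple[str, ...]  # ordered by rank

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class TagSummary:
    n_arrays: int
    n_genes: int
    n_in_3plus: int
    n_in_2: int


def find_duplicate_pairs(
    self_hits: list[AlignmentHit], evalue_max: float = 1e-20
) -> list[DuplicatePair]:
    """Extract undirected duplicate pairs from a self-comparison table.

    Self matches (query == subject) are dropped; the two directions of
    a pair merge into one record keeping the better E-value and bit
    score; pairs above ``evalue_max`` are discarded.
    """
    merged: dict[tuple[str, str], DuplicatePair] = {}
    for h in self_hits:
        if h.query_id == h.subject_id or h.evalue > evalue_max:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        prev = merged.get(key)
        if prev is None:
            merged[key] = DuplicatePair(key[0], key[1], h.evalue, h.bit_score)
        else:
            prev.evalue = min(prev.evalue, h.evalue)
            prev.bit_score = max(prev.bit_score, h.bit_score)
    return [merged[k] for k in sorted(merged)]


def classify_pairs(
    pairs: list[DuplicatePair],
    genes: list[GeneModel],
    proximal_window: int = 10,
) -> tuple[list[DuplicatePair], dict[str, str], list[str]]:
    """Fill each pair's kind and derive per-gene classes and singletons.

    Returns ``(pairs, gene_class, singletons)`` where ``gene_class``
    maps each duplicated gene to its highest-precedence kind and
    ``singletons`` lists genes with no duplicate pair.
    """
    if proximal_window < 2:
        raise ValueError("proximal_window must be >= 2")
    by_id = {g.gene_id: g for g in genes}
    for p in pairs:
        for gid in (p.gene_1, p.gene_2):
            if gid not in by_id:
                raise DataError(f"pair member '{gid}' absent from gene models")
        g1, g2 = by_id[p.gene_1], by_id[p.gene_2]
        if g1.chromosome != g2.chromosome:
            p.kind = "dispersed"
        else:
            gap = abs(g1.rank - g2.rank)
            if gap == 1:
                p.kind = "tandem"
            elif gap <= proximal_window:
                p.kind = "proximal"
            else:
                p.kind = "dispersed"
    rank = {k: i for i, k in enumerate(KIND_PRECEDENCE)}
    gene_class: dict[str, str] = {}
    for p in pairs:
        for gid in (p.gene_1, p.gene_2):
            current = gene_class.get(gid)
            if current is None or rank[p.kind] < rank[current]:
                gene_class[gid] = p.kind
    singletons = sorted(g.gene_id for g in genes if g.gene_id not in gene_class)
    return pairs, gene_class, singletons


def build_tags(
    tandem_pairs: list[DuplicatePair], genes: list[GeneModel]
) -> tuple[list[TandemArray], TagSummary]:
    """Chain tandem pairs into arrays (connected components per chromosome).

    Arrays partition the tandem-duplicated genes; members are ordered by
    rank. The summary splits genes between 2-gene arrays and arrays of
    at least 3 genes.
    """
    by_id = {g.gene_id: g for g in genes}
    graph = nx.Graph()
    for p in tandem_pairs:
        if p.kind != "tandem":
            raise DataError(f"pair ({p.gene_1}, {p.gene_2}) is {p.kind}, not tandem")
        for gid in (p.gene_1, p.gene_2):
            if gid not in by_id:
                raise DataError(f"pair member '{gid}' absent from gene models")
        graph.add_edge(p.gene_1, p.gene_2)
    arrays: list[TandemArray] = []
    for component in nx.connected_components(graph):
        members = sorted(component, key=lambda gid: by_id[gid].rank)
        chroms = {by_id[gid].chromosome for gid in members}
        if len(chroms) != 1:
            raise DataError(f"tandem array spans chromosomes {sorted(chroms)}")
        arrays.append(TandemArray(chromosome=chroms.pop(), member_ids=tuple(members)))
    arrays.sort(key=lambda a: (a.chromosome, by_id[a.member_ids[0]].rank))
    n_genes = sum(a.size for a in arrays)
    n3 = sum(a.size for a in arrays if a.size >= 3)
    n2 = sum(a.size for a in arrays if a.size == 2)
    return arrays, TagSummary(
        n_arrays=len(arrays), n_genes=n_genes, n_in_3plus=n3, n_in_2=n2
    )
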