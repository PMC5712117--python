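"""Core domain types shared across the toolkit.

All record types are plain frozen-ish dataclasses: the readers in
:mod:`vinenc.formats_io` normalize external text formats into these, and
every downstream algorithm consumes them rather than raw rows.
Coordinates follow the GFF3 convention (1-based, inclusive); gene
``rank`` is a 0-based order index along its chromosome assigned on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

#: Sentinel chromosome name for unplaced scaffolds in the grapevine
#: reference; anchors touching it are classified separately because a
#: "different chromosome" call against an unplaced bin is meaningless.
CHR_UNKNOWN = "chrUkn"


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a tabular pairwise alignment (blast outfmt-6 style)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bit_score: float


@dataclass(frozen=True)
class DomainHit:
    """One hmmscan hit of a protein query against a Pfam domain model."""

    query_id: str
    domain_accession: str
    evalue: float
    score: float


@dataclass(frozen=True)
class CmHit:
    """One cmscan hit of a transcript against an Rfam covariance model."""

    query_id: str
    model_accession: str
    evalue: float
    score: float


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    fpkm: float


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene with its position and order along a chromosome.

    ``rank`` is assigned on load: genes of one chromosome are sorted by
    ascending start (ties broken by gene_id) and numbered 0..n-1.
    Tandem adjacency and the proximal window are defined on rank, not on
    base-pair distance.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    rank: int = -1

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FoldResult:
    """Parsed RNA secondary-structure prediction: id, dot-bracket, MFE (kcal/mol)."""

    id: str
    dot_bracket: str
    mfe: float


@dataclass(frozen=True)
class ClusterAssignment:
    cluster_id: int
    member_ids: tuple[str, ...]
    representative_id: str


class Concordance(str, Enum):
    """Chromosome agreement class of an anchor pair."""

    SAME = "same_chromosome"
    DIFFERENT = "different_chromosome"
    CHR_UNKNOWN = "involves_chrUkn"


@dataclass
class AnchorPair:
    """A reciprocal best-hit linkage between gene models of two annotations.

    ``evalue`` is the worse (larger) of the two directional E-values and
    ``bit_score`` the worse (smaller) of the two directional bit scores —
    the conservative summary of the reciprocal evidence.
    """

    a_id: str
    b_id: str
    iteration: int
    evalue: float
    bit_score: float
    concordance: Concordance | None = None


@dataclass(frozen=True)
class AnchorQuality:
    anchor: AnchorPair
    b_length: int
    ratio: float


@dataclass
class TranscriptRecord:
    """A transcript moving through the lncRNA pipeline.

    ``status`` accumulates one ``(stage, kept, reason)`` entry per stage
    the transcript passed through, so any final decision is auditable.
    """

    id: str
    sequence: str
    fpkm: float | None = None
    status: list[tuple[str, bool, str]] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        if not self.sequence:
            return 0.0
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)

    def log(self, stage: str, kept: bool, reason: str = "") -> None:
        self.status.append((stage, kept, reason))


@dataclass(frozen=True)
class GoAnnotation:
    gene_id: str
    domain_accession: str
    go_id: str
    go_class: str  # molecular_function | biological_process | cellular_component


GO_CLASSES = ("molecular_function", "biological_process", "cellular_component")
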