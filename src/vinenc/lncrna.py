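"""De novo lncRNA identification pipeline.

Long non-coding RNAs are operationally defined as transcripts of at
least 200 nt without protein-coding capacity. Starting from de novo
assembled transcripts of two accessions of the same genotype, the
pipeline removes everything with evidence of being something else:

1. redundancy clustering (CD-HIT-style greedy, representatives only),
2. expression filter (FPKM >= 1.50),
3. protein-homology binning per accession (Viridiplantae / non-plant /
   no-hit at E <= 1e-20; only the no-hit bin continues),
4. cross-accession consensus (top hit per query, alignment >= 200 nt,
   keep the longer transcript of each surviving pair),
5. Rfam purge of known structured ncRNA families (cmscan E <= 0.01),
6. minimum-length check (>= 200 nt), and
7. a coding-potential flag: transcripts whose longest six-frame ORF
   reaches 100 codons are set aside as possibly coding. This flag is a
   deliberately simple open-reading-frame heuristic standing in for a
   full coding-potential classifier; flagged transcripts are reported,
   never silently discarded.

Every stage logs a (stage, kept, reason) entry on each transcript and
contributes an audit row, so the shrinking candidate set is fully
accountable: n_in = n_kept + n_removed at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .errors import DataError
from .irbh import _hit_order, rank_hits
from .types import (
    AlignmentHit,
    ClusterAssignment,
    CmHit,
    ExpressionRecord,
    TranscriptRecord,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the pipeline; defaults are the published operating point."""

    cluster_identity: float = 0.90
    fpkm_min: float = 1.50
    protein_evalue_max: float = 1e-20
    min_consensus_alignment: int = 200
    rfam_evalue_max: float = 0.01
    min_lncrna_length: int = 200
    orf_min_codons: int = 100
    #: which accession plays the query role in the consensus step
    consensus_query_side: str = "a"

    def __post_init__(self):
        for name in (
            "cluster_identity",
            "protein_evalue_max",
            "min_consensus_alignment",
            "rfam_evalue_max",
            "min_lncrna_length",
            "orf_min_codons",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fpkm_min < 0:
            raise ValueError("fpkm_min must be non-negative")


@dataclass(frozen=True)
class StageCount:
    stage: str
    n_in: int
    n_kept: int
    n_removed: int


@dataclass
class PipelineResult:
    final: list[TranscriptRecord]
    flagged: list[TranscriptRecord]
    audit: list[StageCount] = field(default_factory=list)
    bins: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    @property
    def final_ids(self) -> set[str]:
        return {t.id for t in self.final}


# ---------------------------------------------------------------------------
# stage 1: redundancy clustering (greedy, CD-HIT style)

def pairwise_identity(seq1: str, seq2: str) -> float:
    """Alignment identity of two sequences over the shorter one.

    The shorter sequence is aligned inside the longer (infix alignment,
    exact edit-distance dynamic programming via edlib) and the identity
    is ``1 − edits / len(shorter)``, clamped at 0. A redundant fragment
    of a longer transcript therefore scores close to 1 against its
    source, matching CD-HIT's identity-over-the-shorter-sequence
    semantics.
    """
    if not seq1 or not seq2:
        return 0.0
    a = seq1.upper().replace("U", "T")
    b = seq2.upper().replace("U", "T")
    if len(a) > len(b):
        a, b = b, a
    dist = edlib.align(a, b, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / len(a))


def cluster_greedy(
    transcripts: list[TranscriptRecord], identity: float = 0.90
) -> list[ClusterAssignment]:
    """Greedy length-sorted clustering; founders are representatives.

    Sequences are visited longest-first (ties by id); each joins the
    first cluster whose representative it matches at >= ``identity``
    over the shorter sequence, else founds a new cluster. Only
    representatives flow down the pipeline. This reproduces the greedy
    scheme of cd-hit-est at desk scale; an externally produced .clstr
    file can be supplied instead.
    """
    if not 0.5 < identity <= 1.0:
        raise ValueError("identity must be in (0.5, 1.0]")
    order = sorted(transcripts, key=lambda t: (-t.length, t.id))
    clusters: list[dict] = []
    for t in order:
        for c in clusters:
            if pairwise_identity(t.sequence, c["rep_seq"]) >= identity:
                c["members"].append(t.id)
                break
        else:
            clusters.append({"rep": t.id, "rep_seq": t.sequence, "members": [t.id]})
    return [
        ClusterAssignment(
            cluster_id=i, member_ids=tuple(c["members"]), representative_id=c["rep"]
        )
        for i, c in enumerate(clusters)
    ]


def apply_clusters(
    transcripts: list[TranscriptRecord], clusters: list[ClusterAssignment], stage: str = "cluster"
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Partition transcripts into representatives (kept) and redundant copies."""
    reps = {c.representative_id for c in clusters}
    kept, removed = [], []
    for t in transcripts:
        if t.id in reps:
            t.log(stage, True, "representative")
            kept.append(t)
        else:
            t.log(stage, False, "redundant")
            removed.append(t)
    return kept, removed


# ---------------------------------------------------------------------------
# stage 2: expression filter


def filter_expression(
    transcripts: list[TranscriptRecord],
    expression: list[ExpressionRecord],
    fpkm_min: float = 1.50,
    stage: str = "expression",
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Keep transcripts with FPKM >= ``fpkm_min`` (inclusive boundary).

    A transcript without an expression record cannot demonstrate
    expression and is removed with reason ``no_expression_record``.
    """
    fpkm = {e.transcript_id: e.fpkm for e in expression}
    kept, removed = [], []
    for t in transcripts:
        if t.id not in fpkm:
            t.log(stage, False, "no_expression_record")
            removed.append(t)
            continue
        t.fpkm = fpkm[t.id]
        if t.fpkm >= fpkm_min:
            t.log(stage, True, f"fpkm={t.fpkm:g}")
            kept.append(t)
        else:
            t.log(stage, False, f"fpkm={t.fpkm:g}<{fpkm_min:g}")
            removed.append(t)
    return kept, removed


# ---------------------------------------------------------------------------
# stage 3: protein-homology binning


def organism_code(subject_id: str) -> str:
    """Extract the organism mnemonic from a protein subject id.

    UniProt-style ids carry the organism as the suffix of the entry name
    (``sp|P12345|NAME_VITVI`` or plain ``NAME_VITVI`` -> ``VITVI``).
    """
    name = subject_id.rsplit("|", 1)[-1]
    return name.rsplit("_", 1)[-1]


def classify_coding(
    transcripts: list[TranscriptRecord],
    protein_hits: list[AlignmentHit],
    taxon_map: dict[str, str],
    evalue_max: float = 1e-20,
    stage: str = "coding",
) -> dict[str, list[TranscriptRecord]]:
    """Bin transcripts by their best protein hit: plant / non_plant / no_hit.

    Per transcript the single best hit (bit score, E-value, identity
    ranking) among hits with E <= ``evalue_max`` decides the bin via
    ``taxon_map``; transcripts without a qualifying hit land in
    ``no_hit`` — the only bin that continues down the pipeline.
    """
    ranked = rank_hits(protein_hits, evalue_max)
    bins: dict[str, list[TranscriptRecord]] = {"plant": [], "non_plant": [], "no_hit": []}
    for t in transcripts:
        hits = ranked.get(t.id)
        if not hits:
            t.log(stage, True, "no_hit")
            bins["no_hit"].append(t)
            continue
        best = hits[0]
        code = organism_code(best.subject_id)
        if code not in taxon_map:
            raise DataError(
                f"organism code '{code}' (subject '{best.subject_id}') missing from taxon map; "
                f"known codes: {sorted(taxon_map)}"
            )
        bin_name = taxon_map[code]
        if bin_name not in ("plant", "non_plant"):
            raise DataError(f"taxon map value '{bin_name}' not in {{plant, non_plant}}")
        t.log(stage, False, f"{bin_name}:{best.subject_id}")
        bins[bin_name].append(t)
    return bins


# ---------------------------------------------------------------------------
# stage 4: cross-accession consensus


def cross_accession_consensus(
    set_a: list[TranscriptRecord],
    set_b: list[TranscriptRecord],
    a_vs_b_hits: list[AlignmentHit],
    min_alignment: int = 200,
    stage: str = "consensus",
) -> list[TranscriptRecord]:
    """Keep transcripts independently observed in both accessions.

    For each query (set A side) only the top hit is accepted; pairs
    aligning over fewer than ``min_alignment`` nt are dropped; for each
    surviving pair the longer of the two transcripts is emitted (ties
    go to the query side), de-duplicated.
    """
    by_id_a = {t.id: t for t in set_a}
    by_id_b = {t.id: t for t in set_b}
    for h in a_vs_b_hits:
        if h.query_id not in by_id_a and h.query_id not in by_id_b:
            raise DataError(f"hit references unknown transcript id '{h.query_id}'")
        if h.subject_id not in by_id_b and h.subject_id not in by_id_a:
            raise DataError(f"hit references unknown transcript id '{h.subject_id}'")
    relevant = [h for h in a_vs_b_hits if h.query_id in by_id_a and h.subject_id in by_id_b]
    best_per_query: dict[str, AlignmentHit] = {}
    for h in relevant:
        prev = best_per_query.get(h.query_id)
        if prev is None or _hit_order(h) < _hit_order(prev):
            best_per_query[h.query_id] = h
    emitted: dict[str, TranscriptRecord] = {}
    matched_ids: set[str] = set()
    for q in sorted(best_per_query):
        h = best_per_query[q]
        if h.alignment_length < min_alignment:
            continue
        ta, tb = by_id_a[h.query_id], by_id_b[h.subject_id]
        winner = tb if tb.length > ta.length else ta
        matched_ids.update((ta.id, tb.id))
        if winner.id not in emitted:
            winner.log(stage, True, f"pair=({ta.id},{tb.id})")
            emitted[winner.id] = winner
    for t in list(set_a) + list(set_b):
        if t.id in matched_ids and t.id not in emitted:
            t.log(stage, False, "shorter_partner")
        elif t.id not in matched_ids:
            t.log(stage, False, "no_cross_accession_match")
    return list(emitted.values())


# ---------------------------------------------------------------------------
# stage 5: Rfam purge


def rfam_filter(
    transcripts: list[TranscriptRecord],
    cm_hits: list[CmHit],
    evalue_max: float = 0.01,
    stage: str = "rfam",
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Remove transcripts matching a known structured ncRNA family.

    A transcript is removed iff it has at least one covariance-model hit
    with E <= ``evalue_max``; the removal reason records the
    best-scoring family.
    """
    by_query: dict[str, list[CmHit]] = {}
    for h in cm_hits:
        if h.evalue <= evalue_max:
            by_query.setdefault(h.query_id, []).append(h)
    kept, removed = [], []
    for t in transcripts:
        hits = by_query.get(t.id)
        if hits:
            best = max(hits, key=lambda h: h.score)
            t.log(stage, False, f"rfam:{best.model_accession}")
            removed.append(t)
        else:
            t.log(stage, True, "")
            kept.append(t)
    return kept, removed


# ---------------------------------------------------------------------------
# stage 6/7: length check and ORF coding flag


def filter_min_length(
    transcripts: list[TranscriptRecord], min_length: int = 200, stage: str = "min_length"
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    kept, removed = [], []
    for t in transcripts:
        if t.length >= min_length:
            t.log(stage, True, "")
            kept.append(t)
        else:
            t.log(stage, False, f"length={t.length}<{min_length}")
            removed.append(t)
    return kept, removed


def longest_orf_codons(sequence: str) -> int:
    """Length in codons (ATG included, stop excluded) of the longest
    complete ORF over all six reading frames."""
    seq = sequence.upper().replace("U", "T")
    best = 0
    for strand_seq in (seq, seq.translate(_COMPLEMENT)[::-1]):
        n = len(strand_seq)
        for frame in range(3):
            start: int | None = None
            for i in range(frame, n - 2, 3):
                codon = strand_seq[i : i + 3]
                if codon in _STOPS:
                    if start is not None:
                        best = max(best, (i - start) // 3)
                        start = None
                elif codon == "ATG" and start is None:
                    start = i
    return best


def orf_coding_flag(
    transcripts: list[TranscriptRecord],
    orf_min_codons: int = 100,
    stage: str = "orf_flag",
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Flag transcripts whose longest six-frame ORF reaches the cutoff.

    Returns (kept, flagged). Flagged transcripts are possibly coding and
    are reported separately rather than silently dropped.
    """
    kept, flagged = [], []
    for t in transcripts:
        codons = longest_orf_codons(t.sequence)
        if codons >= orf_min_codons:
            t.log(stage, False, f"possibly_coding:orf={codons}")
            flagged.append(t)
        else:
            t.log(stage, True, f"orf={codons}")
            kept.append(t)
    return kept, flagged


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineInputs:
    """Evidence tables feeding the pipeline; all generated or parsed upstream."""

    expression_a: list[ExpressionRecord]
    expression_b: list[ExpressionRecord]
    protein_hits_a: list[AlignmentHit]
    protein_hits_b: list[AlignmentHit]
    taxon_map: dict[str, str]
    a_vs_b_hits: list[AlignmentHit]
    cm_hits: list[CmHit]
    clusters_a: list[ClusterAssignment] | None = None
    clusters_b: list[ClusterAssignment] | None = None


def run_pipeline(
    raw_a: list[TranscriptRecord],
    raw_b: list[TranscriptRecord],
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full filter chain on two accessions' transcript sets.

    Stages run in order cluster -> expression -> coding binning (each
    per accession), then cross-accession consensus, Rfam purge, minimum
    length, and the ORF coding flag. The audit table records
    (stage, n_in, n_kept, n_removed) for every stage.
    """
    cfg = config or PipelineConfig()
    audit: list[StageCount] = []
    result_bins: dict[str, dict[str, list[str]]] = {}

    def _record(stage: str, n_in: int, kept: list) -> None:
        audit.append(StageCount(stage, n_in, len(kept), n_in - len(kept)))

    surviving: dict[str, list[TranscriptRecord]] = {}
    for label, transcripts in (("a", raw_a), ("b", raw_b)):
        current = list(transcripts)

        clusters = inputs.clusters_a if label == "a" else inputs.clusters_b
        if clusters is None:
            clusters = cluster_greedy(current, cfg.cluster_identity)
        kept, _ = apply_clusters(current, clusters, stage=f"cluster_{label}")
        _record(f"cluster_{label}", len(current), kept)
        current = kept

        expression = inputs.expression_a if label == "a" else inputs.expression_b
        kept, _ = filter_expression(
            current, expression, cfg.fpkm_min, stage=f"expression_{label}"
        )
        _record(f"expression_{label}", len(current), kept)
        current = kept

        protein_hits = inputs.protein_hits_a if label == "a" else inputs.protein_hits_b
        bins = classify_coding(
            current, protein_hits, inputs.taxon_map, cfg.protein_evalue_max,
            stage=f"coding_{label}",
        )
        result_bins[label] = {k: [t.id for t in v] for k, v in bins.items()}
        _record(f"coding_{label}", len(current), bins["no_hit"])
        surviving[label] = bins["no_hit"]

    if cfg.consensus_query_side == "a":
        set_q, set_s = surviving["a"], surviving["b"]
        pair_hits = inputs.a_vs_b_hits
    else:
        set_q, set_s = surviving["b"], surviving["a"]
        pair_hits = [
            AlignmentHit(h.subject_id, h.query_id, h.percent_identity,
                         h.alignment_length, h.evalue, h.bit_score)
            for h in inputs.a_vs_b_hits
        ]
    consensus = cross_accession_consensus(
        set_q, set_s, pair_hits, cfg.min_consensus_alignment
    )
    _record("consensus", len(set_q) + len(set_s), consensus)

    kept, _ = rfam_filter(consensus, inputs.cm_hits, cfg.rfam_evalue_max)
    _record("rfam", len(consensus), kept)

    kept2, _ = filter_min_length(kept, cfg.min_lncrna_length)
    _record("min_length", len(kept), kept2)

    final, flagged = orf_coding_flag(kept2, cfg.orf_min_codons)
    _record("orf_flag", len(kept2), final)

    final = sorted(final, key=lambda t: t.id)
    return PipelineResult(final=final, flagged=flagged, audit=audit, bins=result_bins)
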