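"""Iterative reciprocal-best-hit (iRBH) anchoring between two annotations.

Classical reciprocal best hits (RBH) pair gene *a* of annotation A with
gene *b* of annotation B when each is the other's top-scoring alignment
hit. When a gene family has several similar copies, a single strong
paralog can absorb the top hit of multiple queries and mask otherwise
valid one-to-one pairs. The iterative variant fixes the RBHs of the
current tables, removes every anchored gene from all remaining rows of
both tables (as query or subject), and repeats; pairs shadowed by a
stronger paralog surface in later rounds. Under the working assumption
that each gene is present in the same number of copies in both
annotations, repeated peeling converges to a one-to-one anchoring.

Hits are ranked by bit score (desc), then E-value (asc), then percent
identity (desc), with subject id as a deterministic final arbiter, so
results are invariant to input row order.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from statistics import fmean

from .errors import DataError
from .types import CHR_UNKNOWN, AlignmentHit, AnchorPair, AnchorQuality, Concordance, GeneModel

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_MAX_ITERATIONS = 25


def _hit_order(h: AlignmentHit):
    return (-h.bit_score, h.evalue, -h.percent_identity, h.subject_id)


def rank_hits(
    hits: list[AlignmentHit], evalue_max: float = DEFAULT_EVALUE_MAX
) -> dict[str, list[AlignmentHit]]:
    """Per-query ranked hit lists with at most one hit per unique subject.

    Hits above ``evalue_max`` are dropped; duplicate (query, subject)
    rows keep only the best row; survivors are ordered by bit score
    desc, E-value asc, percent identity desc, subject id asc.
    """
    per_query: dict[str, dict[str, AlignmentHit]] = defaultdict(dict)
    for h in hits:
        if h.evalue > evalue_max:
            continue
        prev = per_query[h.query_id].get(h.subject_id)
        if prev is None or _hit_order(h) < _hit_order(prev):
            per_query[h.query_id][h.subject_id] = h
    return {
        q: sorted(subj.values(), key=_hit_order)
        for q, subj in sorted(per_query.items())
        if subj
    }


def find_rbh(
    fwd: dict[str, list[AlignmentHit]], rev: dict[str, list[AlignmentHit]]
) -> list[AnchorPair]:
    """Classical single-pass RBH on two ranked hit maps.

    Pair (a, b) is returned iff b is a's first-ranked hit and a is b's
    first-ranked hit. The pair carries the conservative summary of the
    two directional rows: the larger E-value and the smaller bit score.
    """
    pairs: list[AnchorPair] = []
    for a_id in sorted(fwd):
        top_fwd = fwd[a_id][0]
        b_id = top_fwd.subject_id
        rev_list = rev.get(b_id)
        if not rev_list or rev_list[0].subject_id != a_id:
            continue
        top_rev = rev_list[0]
        pairs.append(
            AnchorPair(
                a_id=a_id,
                b_id=b_id,
                iteration=1,
                evalue=max(top_fwd.evalue, top_rev.evalue),
                bit_score=min(top_fwd.bit_score, top_rev.bit_score),
            )
        )
    return pairs


def irbh_anchor(
    fwd_hits: list[AlignmentHit],
    rev_hits: list[AlignmentHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> list[AnchorPair]:
    """Run iterative RBH anchoring until convergence or ``max_iterations``.

    Each round ranks the surviving rows, fixes the classical RBHs, and
    removes every anchored gene from both tables wherever it appears —
    as query or subject — before the next round. ``AnchorPair.iteration``
    records the round at which a pair was fixed.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    fwd = [h for h in fwd_hits if h.evalue <= evalue_max]
    rev = [h for h in rev_hits if h.evalue <= evalue_max]
    anchored_a: set[str] = set()
    anchored_b: set[str] = set()
    out: list[AnchorPair] = []
    for iteration in range(1, max_iterations + 1):
        fwd = [h for h in fwd if h.query_id not in anchored_a and h.subject_id not in anchored_b]
        rev = [h for h in rev if h.query_id not in anchored_b and h.subject_id not in anchored_a]
        new = find_rbh(rank_hits(fwd, evalue_max), rank_hits(rev, evalue_max))
        if not new:
            break
        for p in new:
            p.iteration = iteration
            anchored_a.add(p.a_id)
            anchored_b.add(p.b_id)
        out.extend(new)
    _assert_matching(out)
    return sorted(out, key=lambda p: p.a_id)


def _assert_matching(pairs: list[AnchorPair]) -> None:
    a_ids = [p.a_id for p in pairs]
    b_ids = [p.b_id for p in pairs]
    if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
        raise DataError("anchoring produced a non one-to-one matching")


def classify_concordance(
    pairs: list[AnchorPair],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
) -> tuple[list[AnchorPair], dict[str, int]]:
    """Fill each pair's chromosome-concordance class and tally the classes.

    A pair with either side on the unplaced-scaffold bin ``chrUkn`` is
    classed ``involves_chrUkn``; otherwise the class is decided by
    string equality of the two chromosome names.
    """
    chrom_a = {g.gene_id: g.chromosome for g in genes_a}
    chrom_b = {g.gene_id: g.chromosome for g in genes_b}
    counts = {c.value: 0 for c in Concordance}
    for p in pairs:
        if p.a_id not in chrom_a:
            raise DataError(f"anchored id '{p.a_id}' missing from A gene models")
        if p.b_id not in chrom_b:
            raise DataError(f"anchored id '{p.b_id}' missing from B gene models")
        ca, cb = chrom_a[p.a_id], chrom_b[p.b_id]
        if CHR_UNKNOWN in (ca, cb):
            p.concordance = Concordance.CHR_UNKNOWN
        elif ca == cb:
            p.concordance = Concordance.SAME
        else:
            p.concordance = Concordance.DIFFERENT
        counts[p.concordance.value] += 1
    return pairs, counts


@dataclass(frozen=True)
class QualitySummary:
    mean_ratio: dict[str, float]  # concordance class -> mean bit/length ratio
    mean_evalue: dict[str, float]


def anchor_quality(
    pairs: list[AnchorPair], genes_b: list[GeneModel]
) -> tuple[list[AnchorQuality], QualitySummary]:
    """Bit-score / B-model-length quality ratio per anchor, plus class means.

    A low ratio means the reciprocal alignment covers its legacy model
    weakly — the signature of anchors that land on a different
    chromosome. Means are reported for the placed (non-chrUkn) classes.
    """
    length_b = {g.gene_id: g.length for g in genes_b}
    qualities: list[AnchorQuality] = []
    for p in pairs:
        if p.b_id not in length_b:
            raise DataError(f"anchored id '{p.b_id}' missing from B gene models")
        blen = length_b[p.b_id]
        if blen <= 0:
            raise DataError(f"zero-length model '{p.b_id}'")
        qualities.append(AnchorQuality(anchor=p, b_length=blen, ratio=p.bit_score / blen))
    mean_ratio: dict[str, float] = {}
    mean_evalue: dict[str, float] = {}
    for cls in (Concordance.SAME, Concordance.DIFFERENT):
        members = [q for q in qualities if q.anchor.concordance is cls]
        if members:
            mean_ratio[cls.value] = fmean(q.ratio for q in members)
            mean_evalue[cls.value] = fmean(q.anchor.evalue for q in members)
    return qualities, QualitySummary(mean_ratio=mean_ratio, mean_evalue=mean_evalue)


def rescue_unsupported(
    unanchored_b_ids: set[str],
    fwd_hits: list[AlignmentHit],
    rev_hits: list[AlignmentHit],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    unsupported_a_ids: set[str] | None = None,
) -> list[tuple[str, str, bool]]:
    """Single-pass RBH rescue for legacy models left without an anchor.

    The search is restricted to the given unanchored B ids (and, when
    provided, to the A-side models lacking expression support). Each
    rescue is labeled with chromosome agreement; a rescue touching
    ``chrUkn`` on either side is labeled discordant by convention.
    """
    def keep_a(aid: str) -> bool:
        return unsupported_a_ids is None or aid in unsupported_a_ids

    fwd = [
        h for h in fwd_hits
        if h.subject_id in unanchored_b_ids and keep_a(h.query_id)
    ]
    rev = [
        h for h in rev_hits
        if h.query_id in unanchored_b_ids and keep_a(h.subject_id)
    ]
    pairs = find_rbh(rank_hits(fwd, evalue_max), rank_hits(rev, evalue_max))
    chrom_a = {g.gene_id: g.chromosome for g in genes_a}
    chrom_b = {g.gene_id: g.chromosome for g in genes_b}
    rescues: list[tuple[str, str, bool]] = []
    for p in pairs:
        ca = chrom_a.get(p.a_id)
        cb = chrom_b.get(p.b_id)
        if ca is None or cb is None:
            raise DataError(f"rescued pair ({p.a_id}, {p.b_id}) missing from gene models")
        same = ca == cb and CHR_UNKNOWN not in (ca, cb)
        rescues.append((p.b_id, p.a_id, same))
    return rescues
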