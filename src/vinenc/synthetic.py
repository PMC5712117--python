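"""Synthetic fixture generator with planted ground truth.

Every input the toolkit consumes — transcript FASTAs for two accessions,
expression tables, protein/cross-accession/self alignment tables,
cmscan and hmmscan hit tables, fold results, two GFF3 annotations with
planted orthologs, and a Pfam→GO mapping — can be generated here at
desk scale, deterministically from a seed, together with a truth table
that records what every record *is* and where the pipeline is expected
to dispose of it.

The generated conditions mirror the contrasts the pipeline is built to
exploit: noncoding transcripts are shorter and lower-GC than coding
ones, their planted per-nucleotide folding energies are higher (less
stable), coding transcripts carry plant-protein homology below the
removal threshold, housekeeping structural ncRNAs carry Rfam hits, and
cross-accession partners align over at least 200 nt. Alignment scores
are ordinally consistent (better homology → better score); no alignment
engine is simulated.

Every default bundle plants *boundary probes*: records sitting exactly
on, or one step past, each decision threshold (FPKM 1.49 vs 1.50,
alignment 199 vs 200 nt, Rfam E 0.01 vs 0.011, protein E 1e-20 vs just
above). Probes whose value falls on the removal side carry truth class
``decoy``; probes that must survive are class ``noncoding`` with a
probe tag. This pins the inclusivity of every threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .lncrna import PipelineInputs, longest_orf_codons
from .types import (
    AlignmentHit,
    CmHit,
    DomainHit,
    ExpressionRecord,
    FoldResult,
    GeneModel,
    SequenceRecord,
)
from .formats_io import assign_ranks

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]

TAXON_MAP = {
    "VITVI": "plant",
    "SOYBN": "plant",
    "ARATH": "plant",
    "HUMAN": "non_plant",
    "YEAST": "non_plant",
    "ECOLI": "non_plant",
}
_PLANT_CODES = ("VITVI", "SOYBN", "ARATH")
_NONPLANT_CODES = ("HUMAN", "YEAST", "ECOLI")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generator; defaults are the study conditions.

    Lengths are log-normal per class (coding median ≈ 900 nt, noncoding
    ≈ 450 nt, both floored at 250 nt so the 200-nt operational length
    definition never decides a keeper's fate); GC means 0.45 / 0.38 /
    0.55 for coding / noncoding / housekeeping; planted per-nucleotide
    fold energies use the published group summaries (−0.276 ± 0.026 vs
    −0.210 ± 0.041 kcal/mol/nt); expression is log-normal floored at
    1.6 FPKM for keepers.
    """

    seed: int = 1992
    n_coding: int = 40
    n_noncoding: int = 24
    n_housekeeping: int = 6
    n_redundant: int = 4
    coding_len_mu: float = 6.8
    coding_len_sigma: float = 0.30
    noncoding_len_mu: float = 6.1
    noncoding_len_sigma: float = 0.30
    min_length: int = 250
    gc_coding: float = 0.45
    gc_noncoding: float = 0.38
    gc_housekeeping: float = 0.55
    mfe_coding_mean: float = -0.276
    mfe_coding_sd: float = 0.026
    mfe_noncoding_mean: float = -0.210
    mfe_noncoding_sd: float = 0.041
    fpkm_log_mu: float = 1.6
    fpkm_log_sigma: float = 0.8
    fpkm_floor: float = 1.6
    homology_noise_rate: float = 0.15
    non_plant_fraction: float = 0.15
    orf_min_codons: int = 100
    n_genes: int = 36
    n_chromosomes: int = 4


@dataclass
class TruthRow:
    transcript_id: str
    accession: str  # "a" | "b"
    cls: str  # coding | noncoding | housekeeping_ncRNA | decoy
    length: int
    planted_fpkm: float | None
    partner_id: str | None = None
    probe: str = ""
    #: pipeline stage expected to dispose of this record; "final" means
    #: it must appear in the final lncRNA set
    removed_at: str = ""
    chromosome: str = ""


@dataclass
class TruthTable:
    rows: dict[str, TruthRow] = field(default_factory=dict)
    #: planted one-to-one ortholog map for the anchoring tables
    ortholog_map: dict[str, str] = field(default_factory=dict)
    #: planted tandem arrays (tuples of gene ids, rank-ordered)
    tandem_arrays: list[tuple[str, ...]] = field(default_factory=list)
    #: planted GO instance counts per ontology class
    go_class_counts: dict[str, int] = field(default_factory=dict)

    def add(self, row: TruthRow) -> None:
        if row.transcript_id in self.rows:
            raise ValueError(f"duplicate truth row '{row.transcript_id}'")
        self.rows[row.transcript_id] = row

    @property
    def expected_final_ids(self) -> set[str]:
        return {tid for tid, r in self.rows.items() if r.removed_at == "final"}

    def ids_of_class(self, cls: str) -> set[str]:
        return {tid for tid, r in self.rows.items() if r.cls == cls}


@dataclass
class Evidence:
    expression_a: list[ExpressionRecord]
    expression_b: list[ExpressionRecord]
    protein_hits_a: list[AlignmentHit]
    protein_hits_b: list[AlignmentHit]
    a_vs_b_hits: list[AlignmentHit]
    cm_hits: list[CmHit]
    folds: dict[str, FoldResult]
    taxon_map: dict[str, str]
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    fwd_hits: list[AlignmentHit]
    rev_hits: list[AlignmentHit]
    self_hits: list[AlignmentHit]
    domain_hits: list[DomainHit]
    pfam2go: dict[str, list[tuple[str, str]]]


@dataclass
class Bundle:
    config: SimConfig
    transcripts_a: list[SequenceRecord]
    transcripts_b: list[SequenceRecord]
    truth: TruthTable
    evidence: Evidence

    def transcript_records(self):
        """Fresh pipeline-ready ``TranscriptRecord`` lists for both accessions."""
        from .types import TranscriptRecord

        return (
            [TranscriptRecord(id=r.id, sequence=r.sequence) for r in self.transcripts_a],
            [TranscriptRecord(id=r.id, sequence=r.sequence) for r in self.transcripts_b],
        )

    def pipeline_inputs(self) -> PipelineInputs:
        ev = self.evidence
        return PipelineInputs(
            expression_a=ev.expression_a,
            expression_b=ev.expression_b,
            protein_hits_a=ev.protein_hits_a,
            protein_hits_b=ev.protein_hits_b,
            taxon_map=ev.taxon_map,
            a_vs_b_hits=ev.a_vs_b_hits,
            cm_hits=ev.cm_hits,
        )


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _noncoding_seq(rng: np.random.Generator, length: int, gc: float, orf_max: int) -> str:
    """Random sequence rejected until its longest ORF stays below orf_max."""
    for _ in range(80):
        seq = _random_seq(rng, length, gc)
        if longest_orf_codons(seq) < orf_max:
            return seq
    raise RuntimeError("could not draw an ORF-free sequence; lengths too large?")


def _coding_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence with an embedded complete ORF (>= 120 codons).

    ORF codons are drawn base-by-base at the target GC (stop codons and
    internal ATGs redrawn) so the whole transcript keeps the class GC.
    """
    n_codons = min(max((length - 60) // 3, 120), 400)
    body: list[str] = []
    while len(body) < n_codons - 1:
        codon = _random_seq(rng, 3, gc)
        if codon not in _STOPS and codon != "ATG":
            body.append(codon)
    orf = "ATG" + "".join(body) + "TGA"
    flank = length - len(orf)
    if flank < 0:
        return orf[:length]
    left = flank // 2
    return _random_seq(rng, left, gc) + orf + _random_seq(rng, flank - left, gc)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    n_mut = max(1, int(len(seq) * rate))
    for i in rng.choice(len(seq), size=n_mut, replace=False):
        out[i] = "ACGT"[(("ACGT".index(out[i])) + 1 + rng.integers(3)) % 4]
    return "".join(out)


def _length(rng: np.random.Generator, mu: float, sigma: float, floor: int) -> int:
    return max(floor, int(rng.lognormal(mu, sigma)))


def _fpkm(rng: np.random.Generator, cfg: SimConfig) -> float:
    return round(max(cfg.fpkm_floor, float(rng.lognormal(cfg.fpkm_log_mu, cfg.fpkm_log_sigma))), 2)


# ---------------------------------------------------------------------------
# transcript generation


def gen_transcripts(cfg: SimConfig | None = None):
    """Generate both accessions' transcript sets and the truth table.

    Returns ``(records_a, records_b, truth)``. Noncoding and
    housekeeping transcripts come in cross-accession pairs whose lengths
    deliberately differ (so the consensus winner is unambiguous);
    redundant fragments, boundary probes and rule-violating decoys are
    planted alongside.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = TruthTable()
    rec_a: list[SequenceRecord] = []
    rec_b: list[SequenceRecord] = []

    def add(acc, tid, seq, cls, fpkm, partner=None, probe="", removed_at=""):
        (rec_a if acc == "a" else rec_b).append(SequenceRecord(id=tid, sequence=seq))
        truth.add(
            TruthRow(
                transcript_id=tid, accession=acc, cls=cls, length=len(seq),
                planted_fpkm=fpkm, partner_id=partner, probe=probe,
                removed_at=removed_at,
            )
        )
        return tid

    def add_pair(stem, cls, seq_len, gc, removed_at_winner, probe="",
                 fpkm_a=None, fpkm_b=None):
        """Plant a cross-accession partner pair.

        One side (chosen at random) is 30 nt longer, so the consensus
        winner is always unambiguous; the partner is a 2%-mutated copy
        of the shared core. ``cls`` values ``decoy_nc``/``decoy_orf``
        map to truth class ``decoy`` (ORF-free resp. ORF-bearing).
        """
        a_longer = bool(rng.integers(2))
        len_a = seq_len + (30 if a_longer else 0)
        len_b = seq_len + (0 if a_longer else 30)
        orf_free = cls in ("noncoding", "housekeeping_ncRNA", "decoy_nc")
        if orf_free:
            seq_a = _noncoding_seq(rng, len_a, gc, cfg.orf_min_codons)
        else:
            seq_a = _coding_seq(rng, len_a, gc)
        core = min(len_a, len_b)
        seq_b = _mutate(rng, seq_a[:core], 0.02)
        if len_b > core:
            seq_b += _random_seq(rng, len_b - core, gc)
        if orf_free:
            for _ in range(10):  # mutation must not manufacture a long ORF
                if longest_orf_codons(seq_b) < cfg.orf_min_codons:
                    break
                seq_b = _mutate(rng, seq_a[:core], 0.02)
            else:
                seq_b = _noncoding_seq(rng, len_b, gc, cfg.orf_min_codons)
        elif cls == "decoy_orf":
            for _ in range(10):  # mutation must not destroy the planted ORF
                if longest_orf_codons(seq_b) >= cfg.orf_min_codons:
                    break
                seq_b = _mutate(rng, seq_a[:core], 0.02)
            else:
                seq_b = _coding_seq(rng, len_b, gc)
        aid, bid = f"A_{stem}", f"B_{stem}"
        winner = aid if len_a >= len_b else bid
        true_cls = cls if cls in ("noncoding", "housekeeping_ncRNA") else "decoy"
        add("a", aid, seq_a,
            true_cls, fpkm_a if fpkm_a is not None else _fpkm(rng, cfg),
            partner=bid, probe=probe,
            removed_at=removed_at_winner if winner == aid else "consensus")
        add("b", bid, seq_b,
            true_cls, fpkm_b if fpkm_b is not None else _fpkm(rng, cfg),
            partner=aid, probe=probe,
            removed_at=removed_at_winner if winner == bid else "consensus")
        return aid, bid, winner

    # --- coding transcripts (independent per accession)
    for acc in ("a", "b"):
        for i in range(cfg.n_coding):
            length = _length(rng, cfg.coding_len_mu, cfg.coding_len_sigma, cfg.min_length)
            seq = _coding_seq(rng, length, cfg.gc_coding)
            add(acc, f"{acc.upper()}_cod_{i:04d}", seq, "coding",
                _fpkm(rng, cfg), removed_at=f"coding_{acc}")

    # --- planted noncoding pairs (the expected final set comes from these)
    for i in range(cfg.n_noncoding):
        length = _length(rng, cfg.noncoding_len_mu, cfg.noncoding_len_sigma, cfg.min_length)
        add_pair(f"nc_{i:04d}", "noncoding", length, cfg.gc_noncoding, "final")

    # --- housekeeping structural ncRNAs: removed by the Rfam stage
    for i in range(cfg.n_housekeeping):
        length = _length(rng, cfg.noncoding_len_mu, cfg.noncoding_len_sigma, cfg.min_length)
        add_pair(f"hk_{i:04d}", "housekeeping_ncRNA", length, cfg.gc_housekeeping, "rfam")

    # --- redundant fragments: collapse into their source at clustering
    nc_sources = [r for r in rec_a if r.id.startswith("A_nc_")][: cfg.n_redundant]
    for src in nc_sources:
        frag_len = max(cfg.min_length - 40, int(src.length * 0.8))
        frag = _mutate(rng, src.sequence[:frag_len], 0.02)
        add("a", f"{src.id}__r", frag, "decoy", _fpkm(rng, cfg),
            partner=src.id, probe="redundant", removed_at="cluster_a")

    # --- boundary probes and decoys (mandatory in every bundle)
    nclen = lambda: _length(rng, cfg.noncoding_len_mu, cfg.noncoding_len_sigma, cfg.min_length)
    # FPKM boundary: 1.49 removed, 1.50 kept
    add("a", "A_dec_fpkm", _noncoding_seq(rng, nclen(), cfg.gc_noncoding, cfg.orf_min_codons),
        "decoy", 1.49, probe="fpkm_1.49", removed_at="expression_a")
    add_pair("probe_fpkm", "noncoding", nclen(), cfg.gc_noncoding, "final",
             probe="fpkm_1.50", fpkm_a=1.50, fpkm_b=_fpkm(rng, cfg))
    # missing expression record
    add("a", "A_dec_noexpr", _noncoding_seq(rng, nclen(), cfg.gc_noncoding, cfg.orf_min_codons),
        "decoy", None, probe="no_expression", removed_at="expression_a")
    # protein E-value boundary: exactly 1e-20 removed, just above kept
    add("a", "A_dec_prot", _noncoding_seq(rng, nclen(), cfg.gc_noncoding, cfg.orf_min_codons),
        "decoy", _fpkm(rng, cfg), probe="protein_1e-20", removed_at="coding_a")
    add_pair("probe_prot", "noncoding", nclen(), cfg.gc_noncoding, "final",
             probe="protein_above_1e-20")
    # consensus alignment-length boundary: 199 removed, 200 kept
    add_pair("dec_aln", "decoy_nc", nclen(), cfg.gc_noncoding, "consensus",
             probe="alignment_199")
    add_pair("probe_aln", "noncoding", nclen(), cfg.gc_noncoding, "final",
             probe="alignment_200")
    # Rfam boundary: E = 0.01 removed (handled by a housekeeping pair), 0.011 kept
    add_pair("probe_rfam", "noncoding", nclen(), cfg.gc_noncoding, "final",
             probe="rfam_0.011")
    # ORF flag: survives all filters but is possibly coding
    len_orf = max(nclen(), 3 * (cfg.orf_min_codons + 25) + 20)
    add_pair("dec_orf", "decoy_orf", len_orf, cfg.gc_noncoding, "orf_flag",
             probe="orf_flag")
    return rec_a, rec_b, truth


# ---------------------------------------------------------------------------
# evidence generation


def _evalue_bits(rng: np.random.Generator, strong: bool) -> tuple[float, float]:
    if strong:
        return 10.0 ** -float(rng.uniform(30, 60)), float(rng.uniform(200, 500))
    return 10.0 ** -float(rng.uniform(6, 12)), float(rng.uniform(50, 100))


def gen_evidence(truth: TruthTable, cfg: SimConfig | None = None) -> Evidence:
    """Generate every evidence table implied by the truth table.

    A fresh generator seeded at ``cfg.seed + 1`` keeps evidence draws
    decoupled from sequence draws.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    rows = truth.rows

    # expression: every transcript except the no-record decoy
    expression = {"a": [], "b": []}
    for tid, r in rows.items():
        if r.planted_fpkm is not None:
            expression[r.accession].append(ExpressionRecord(tid, r.planted_fpkm))

    # protein homology: coding transcripts get strong plant (or sometimes
    # non-plant) hits far below the 1e-20 threshold; noise hits above the
    # threshold land on noncoding transcripts and must change nothing.
    protein = {"a": [], "b": []}
    for tid, r in rows.items():
        if r.cls == "coding":
            non_plant = rng.random() < cfg.non_plant_fraction
            codes = _NONPLANT_CODES if non_plant else _PLANT_CODES
            best_code = codes[int(rng.integers(len(codes)))]
            ev, bits = _evalue_bits(rng, strong=True)
            protein[r.accession].append(
                AlignmentHit(tid, f"P{rng.integers(1e5):05d}_{best_code}",
                             float(rng.uniform(70, 99)), r.length // 2, ev, bits)
            )
            # a dominated secondary hit
            protein[r.accession].append(
                AlignmentHit(tid, f"P{rng.integers(1e5):05d}_{_PLANT_CODES[0]}",
                             float(rng.uniform(60, 90)), r.length // 3,
                             ev * 1e3, bits / 2)
            )
        elif r.cls in ("noncoding", "housekeeping_ncRNA") and rng.random() < cfg.homology_noise_rate:
            protein[r.accession].append(
                AlignmentHit(tid, f"P{rng.integers(1e5):05d}_{_PLANT_CODES[1]}",
                             float(rng.uniform(40, 70)), 60,
                             10.0 ** -float(rng.uniform(3, 8)), 40.0)
            )
    # boundary probes
    protein["a"].append(AlignmentHit("A_dec_prot", "P99990_VITVI", 88.0, 150, 1e-20, 120.0))
    for tid in ("A_probe_prot", "B_probe_prot"):
        protein[rows[tid].accession].append(
            AlignmentHit(tid, "P99991_VITVI", 88.0, 150, 1.05e-20, 119.0)
        )

    # cross-accession blastn: one top hit per planted pair
    a_vs_b: list[AlignmentHit] = []
    for tid, r in rows.items():
        if r.accession != "a" or r.partner_id is None or not r.partner_id.startswith("B_"):
            continue
        partner = rows[r.partner_id]
        aln = min(r.length, partner.length)
        if r.probe == "alignment_199":
            aln = 199
        elif r.probe == "alignment_200":
            aln = 200
        a_vs_b.append(
            AlignmentHit(tid, r.partner_id, float(rng.uniform(95, 99.9)), aln,
                         10.0 ** -float(rng.uniform(40, 80)), 2.0 * aln)
        )
        # dominated cross-noise against a wrong partner
        if rng.random() < cfg.homology_noise_rate:
            others = [x for x, q in rows.items()
                      if q.accession == "b" and q.partner_id and x != r.partner_id
                      and q.probe != "redundant"]
            if others:
                wrong = others[int(rng.integers(len(others)))]
                a_vs_b.append(
                    AlignmentHit(tid, wrong, float(rng.uniform(80, 90)),
                                 max(200, aln // 2), 1e-20, 0.8 * aln)
                )

    # cmscan: housekeeping ncRNAs below threshold (one exactly at 0.01),
    # the Rfam probe just above it
    cm_hits: list[CmHit] = []
    hk_ids = sorted(tid for tid, r in rows.items() if r.cls == "housekeeping_ncRNA")
    for i, tid in enumerate(hk_ids):
        ev = 0.01 if i == 0 else 10.0 ** -float(rng.uniform(2.1, 6))
        cm_hits.append(CmHit(tid, f"RF{rng.integers(10, 2600):05d}", ev, float(rng.uniform(30, 90))))
    for tid in ("A_probe_rfam", "B_probe_rfam"):
        cm_hits.append(CmHit(tid, "RF00005", 0.011, 25.0))

    # folds: planted per-nucleotide energies by class
    folds: dict[str, FoldResult] = {}
    for tid, r in sorted(rows.items()):
        if r.cls == "coding":
            per_nt = rng.normal(cfg.mfe_coding_mean, cfg.mfe_coding_sd)
        else:
            per_nt = rng.normal(cfg.mfe_noncoding_mean, cfg.mfe_noncoding_sd)
        per_nt = min(per_nt, -0.01)
        folds[tid] = FoldResult(id=tid, dot_bracket="." * r.length,
                                mfe=round(per_nt * r.length, 2))

    genes_a, genes_b, fwd, rev, self_hits = _gen_gene_models(truth, cfg, rng)
    domain_hits, pfam2go = _gen_domains(truth, cfg, rng, genes_a)

    return Evidence(
        expression_a=expression["a"], expression_b=expression["b"],
        protein_hits_a=protein["a"], protein_hits_b=protein["b"],
        a_vs_b_hits=a_vs_b, cm_hits=cm_hits, folds=folds, taxon_map=dict(TAXON_MAP),
        genes_a=genes_a, genes_b=genes_b, fwd_hits=fwd, rev_hits=rev,
        self_hits=self_hits, domain_hits=domain_hits, pfam2go=pfam2go,
    )


def _gen_gene_models(truth: TruthTable, cfg: SimConfig, rng: np.random.Generator):
    """Two gene-model annotations with planted orthologs, a masked paralog
    family (recoverable only by the iterative pass), concordance cases,
    and planted tandem arrays in the self-comparison table."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genes_a, genes_b = [], []
    fwd, rev, self_hits = [], [], []
    n = cfg.n_genes
    for i in range(n):
        chrom = chroms[i % len(chroms)]
        start = 1000 * (i // len(chroms) + 1)
        length = int(rng.uniform(600, 3000))
        # concordance cases: a couple of B genes unplaced, one migrated
        chrom_b = chrom
        if i in (n - 1, n - 2):
            chrom_b = "chrUkn"
        elif i == n - 3:
            chrom_b = chroms[(i + 1) % len(chroms)]
        genes_a.append(GeneModel(f"Ag_{i:03d}", chrom, start, start + length, "+"))
        genes_b.append(GeneModel(f"Bg_{i:03d}", chrom_b, start + 17, start + 17 + length, "+"))
        truth.ortholog_map[f"Ag_{i:03d}"] = f"Bg_{i:03d}"

    # ortholog hit tables: mutual tops, plus strictly dominated decoy rows
    for i in range(n):
        ev, bits = _evalue_bits(rng, strong=True)
        a, b = f"Ag_{i:03d}", f"Bg_{i:03d}"
        ident = float(rng.uniform(85, 99))
        fwd.append(AlignmentHit(a, b, ident, 400, ev, bits))
        rev.append(AlignmentHit(b, a, ident, 400, ev * 1.5, bits - 1))
        if rng.random() < 0.4:
            j = int(rng.integers(n))
            if j != i:
                fwd.append(AlignmentHit(a, f"Bg_{j:03d}", ident - 10, 300, ev * 1e5, bits * 0.6))
                rev.append(AlignmentHit(f"Bg_{j:03d}", a, ident - 10, 300, ev * 1e5, bits * 0.6))
    # masked paralog family: pair 1 shadows pair 0 until round 2
    m0, m1 = f"Ag_{0:03d}", f"Ag_{1:03d}"
    b0, b1 = f"Bg_{0:03d}", f"Bg_{1:03d}"
    fwd = [h for h in fwd if h.query_id not in (m0, m1)]
    rev = [h for h in rev if h.subject_id not in (m0, m1)]
    fwd += [
        AlignmentHit(m0, b0, 99.0, 400, 1e-60, 1000.0),
        AlignmentHit(m1, b0, 97.0, 400, 1e-55, 990.0),
        AlignmentHit(m1, b1, 90.0, 400, 1e-40, 700.0),
    ]
    rev += [
        AlignmentHit(b0, m0, 99.0, 400, 1e-60, 1000.0),
        AlignmentHit(b0, m1, 97.0, 400, 1e-55, 990.0),
        AlignmentHit(b1, m1, 90.0, 400, 1e-40, 700.0),
    ]

    # planted tandem arrays on annotation A, using rank adjacency:
    # ranks within a chromosome follow start order, i.e. Ag_i, Ag_{i+4}, ...
    genes_a = assign_ranks(genes_a)
    genes_b = assign_ranks(genes_b)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes_a:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for v in by_chrom.values():
        v.sort(key=lambda g: g.rank)
    c1, c2 = chroms[0], chroms[1]
    chain = [g.gene_id for g in by_chrom[c1][:3]]          # 3-gene array
    pair2 = [g.gene_id for g in by_chrom[c2][:2]]          # 2-gene array
    prox = [by_chrom[c1][4].gene_id, by_chrom[c1][7].gene_id]   # Δrank 3: proximal
    disp = [by_chrom[c1][-1].gene_id, by_chrom[c2][-1].gene_id]  # dispersed

    def self_pair(g1, g2, ev=1e-30, bits=250.0):
        self_hits.append(AlignmentHit(g1, g2, 92.0, 350, ev, bits))
        self_hits.append(AlignmentHit(g2, g1, 92.0, 350, ev, bits))

    self_pair(chain[0], chain[1])
    self_pair(chain[1], chain[2])
    self_pair(*pair2)
    self_pair(*prox)
    self_pair(*disp)
    self_pair(by_chrom[c2][2].gene_id, by_chrom[c2][3].gene_id, ev=1e-10)  # above threshold
    self_hits.append(AlignmentHit(chain[0], chain[0], 100.0, 500, 0.0, 999.0))  # self match
    truth.tandem_arrays = [tuple(chain), tuple(pair2)]
    return genes_a, genes_b, fwd, rev, self_hits


_PFAM2GO_PLANT = {
    "PF00001": [("GO:0004930", "molecular_function"), ("GO:0007186", "biological_process")],
    "PF00005": [("GO:0005524", "molecular_function")],
    "PF00069": [("GO:0004672", "molecular_function"), ("GO:0006468", "biological_process")],
    "PF00067": [("GO:0016020", "cellular_component")],
    # PF99999 deliberately unmapped
}


def _gen_domains(truth: TruthTable, cfg: SimConfig, rng: np.random.Generator,
                 genes_a: list[GeneModel]):
    """hmmscan-style domain hits over annotation-A genes plus a Pfam→GO map."""
    accs = sorted(_PFAM2GO_PLANT) + ["PF99999"]
    hits: list[DomainHit] = []
    counts = {"molecular_function": 0, "biological_process": 0, "cellular_component": 0}
    for i, g in enumerate(genes_a[: cfg.n_genes // 2]):
        acc = accs[i % len(accs)]
        significant = i % 4 != 3  # every 4th hit fails the E-value filter
        ev = 10.0 ** -float(rng.uniform(6, 30)) if significant else 10.0 ** -float(rng.uniform(1, 4))
        if i % 7 == 0:
            ev = 1e-05 if significant else 2e-05  # boundary pins
        hits.append(DomainHit(g.gene_id, acc, ev, float(rng.uniform(20, 300))))
        if significant:
            for _go, cls in _PFAM2GO_PLANT.get(acc, []):
                counts[cls] += 1
    truth.go_class_counts = counts
    return hits, {k: list(v) for k, v in _PFAM2GO_PLANT.items()}


# ---------------------------------------------------------------------------
# top level


def make_bundle(cfg: SimConfig | None = None) -> Bundle:
    """Generate the full synthetic bundle (transcripts, truth, evidence)."""
    cfg = cfg or SimConfig()
    rec_a, rec_b, truth = gen_transcripts(cfg)
    evidence = gen_evidence(truth, cfg)
    return Bundle(config=cfg, transcripts_a=rec_a, transcripts_b=rec_b,
                  truth=truth, evidence=evidence)


# ---------------------------------------------------------------------------
# serialization to the external text formats


def write_bundle(bundle: Bundle, outdir) -> dict[str, Path]:
    """Write every table of the bundle in its external text format.

    Returns a name → path map. All files re-parse through
    :mod:`vinenc.formats_io` into records equal to the in-memory bundle.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ev = bundle.evidence
    paths: dict[str, Path] = {}

    def _p(name):
        paths[name] = out / name
        return paths[name]

    from . import formats_io as fio

    fio.write_fasta(bundle.transcripts_a, _p("transcripts_a.fasta"))
    fio.write_fasta(bundle.transcripts_b, _p("transcripts_b.fasta"))

    for name, recs in (("expression_a.tsv", ev.expression_a),
                       ("expression_b.tsv", ev.expression_b)):
        with open(_p(name), "w") as fh:
            fh.write("transcript_id\tFPKM\n")
            for r in recs:
                fh.write(f"{r.transcript_id}\t{r.fpkm:g}\n")

    def _blast(name, hits):
        with open(_p(name), "w") as fh:
            fh.write("# blast outfmt 6\n")
            for h in hits:
                mism = max(0, int(h.alignment_length * (1 - h.percent_identity / 100)))
                fh.write(
                    f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                    f"{h.alignment_length}\t{mism}\t0\t1\t{h.alignment_length}\t"
                    f"1\t{h.alignment_length}\t{h.evalue:.3g}\t{h.bit_score:.1f}\n"
                )

    _blast("protein_a.tsv", ev.protein_hits_a)
    _blast("protein_b.tsv", ev.protein_hits_b)
    _blast("a_vs_b.tsv", ev.a_vs_b_hits)
    _blast("fwd.tsv", ev.fwd_hits)
    _blast("rev.tsv", ev.rev_hits)
    _blast("self_blast.tsv", ev.self_hits)

    with open(_p("cmscan.tbl"), "w") as fh:
        fh.write("#target name  accession  query name  accession  mdl  mdl from  mdl to"
                 "  seq from  seq to  strand  trunc  pass  gc  bias  score  E-value  inc"
                 "  description of target\n")
        for h in ev.cm_hits:
            fh.write(f"family {h.model_accession} {h.query_id} - cm 1 60 1 60 + no 1 "
                     f"0.45 0.0 {h.score:.1f} {h.evalue:.3g} ! -\n")

    with open(_p("hmmscan.tbl"), "w") as fh:
        fh.write("#target name  accession  query name  accession  E-value  score  bias\n")
        for h in ev.domain_hits:
            fh.write(f"domain {h.domain_accession} {h.query_id} - {h.evalue:.3g} "
                     f"{h.score:.1f} 0.1\n")

    seqs = {r.id: r.sequence for r in bundle.transcripts_a + bundle.transcripts_b}
    with open(_p("folds.txt"), "w") as fh:
        for tid in sorted(ev.folds):
            f = ev.folds[tid]
            fh.write(f">{tid}\n{seqs[tid].replace('T', 'U')}\n{f.dot_bracket} ({f.mfe:.2f})\n")

    def _gff(name, genes):
        with open(_p(name), "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
                fh.write(f"{g.chromosome}\tvinenc_sim\tgene\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}\n")

    _gff("genes_a.gff3", ev.genes_a)
    _gff("genes_b.gff3", ev.genes_b)

    with open(_p("pfam2go.tsv"), "w") as fh:
        for acc in sorted(ev.pfam2go):
            for go_id, cls in ev.pfam2go[acc]:
                fh.write(f"{acc}\t{go_id}\t{cls}\n")

    with open(_p("truth.tsv"), "w") as fh:
        fh.write("transcript_id\taccession\tclass\tlength\tfpkm\tpartner\tprobe\tremoved_at\n")
        for tid in sorted(bundle.truth.rows):
            r = bundle.truth.rows[tid]
            fpkm = "" if r.planted_fpkm is None else f"{r.planted_fpkm:g}"
            fh.write(f"{tid}\t{r.accession}\t{r.cls}\t{r.length}\t{fpkm}\t"
                     f"{r.partner_id or ''}\t{r.probe}\t{r.removed_at}\n")
    return paths
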