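"""Readers and writers for the external text formats the toolkit consumes.

Each reader normalizes one standard dialect into the domain types of
:mod:`vinenc.types`:

===============  =====================================================
FASTA            ``read_fasta`` / ``write_fasta`` (via Bio.SeqIO)
blast outfmt 6   ``read_blast_tab`` — 12-column tab-separated hits
hmmscan tblout   ``read_hmmscan`` — whitespace table, '#' comments
cmscan tblout    ``read_cmscan`` — whitespace table, '#' comments
expression TSV   ``read_expression`` — (transcript_id, FPKM)
GFF3             ``read_gff3_genes`` — gene features with order ranks
RNAfold output   ``read_rnafold`` — id / sequence / dot-bracket (MFE)
CD-HIT .clstr    ``read_clstr`` — '>Cluster n' sections, '*' = rep
pfam2go          ``read_pfam2go`` — Pfam accession → GO terms
===============  =====================================================

All readers accept plain or gzip-compressed paths, skip comment lines,
tolerate extra trailing columns (tool-version drift), and raise
:class:`~vinenc.errors.FormatError` with a file position on malformed
input. Parsing failures never silently drop rows.
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from collections import defaultdict
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError
from .types import (
    AlignmentHit,
    ClusterAssignment,
    CmHit,
    DomainHit,
    ExpressionRecord,
    FoldResult,
    GeneModel,
    SequenceRecord,
)

_NUCLEOTIDES = set("ACGTUN")


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into :class:`SequenceRecord` s.

    Sequences are upper-cased; ids must be unique within the file and
    every header must be followed by at least one sequence line.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    dupes: list[str] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"header '{rec.id}' has no sequence", path=path)
            bad = set(seq) - _NUCLEOTIDES
            if bad:
                raise FormatError(
                    f"record '{rec.id}' contains non-nucleotide characters {sorted(bad)}",
                    path=path,
                )
            if rec.id in seen:
                dupes.append(rec.id)
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    if dupes:
        raise FormatError(f"duplicate sequence ids: {sorted(set(dupes))}", path=path)
    if not records:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
    return records


def write_fasta(records, path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id,
                      description=getattr(r, "description", "") or "")
        for r in records
    ]
    with open(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# blast outfmt 6


def read_blast_tab(path) -> list[AlignmentHit]:
    """Read 12-column tab-separated blast output (outfmt 6).

    Columns 1, 2, 3, 4, 11 and 12 map to query, subject, percent
    identity, alignment length, E-value and bit score; the remaining
    standard columns (mismatches, gap opens, coordinates) are validated
    for presence but otherwise ignored, and extra trailing columns are
    tolerated.
    """
    hits: list[AlignmentHit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"expected >= 12 tab-separated columns, got {len(cols)}",
                    path=path,
                    line=lineno,
                )
            try:
                hit = AlignmentHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            except ValueError as exc:
                raise FormatError(f"unparseable numeric field: {exc}", path=path, line=lineno)
            if hit.evalue < 0:
                raise FormatError("negative E-value", path=path, line=lineno)
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# HMMER / Infernal tblout


def _tblout_rows(path, min_cols: int):
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < min_cols:
                raise FormatError(
                    f"expected >= {min_cols} whitespace-separated columns, got {len(cols)}",
                    path=path,
                    line=lineno,
                )
            yield lineno, cols


def read_hmmscan(path) -> list[DomainHit]:
    """Read hmmscan ``--tblout`` output.

    Column layout: target name, target accession, query name, query
    accession, full-sequence E-value, full-sequence score, ... — the
    domain (target) accession, query id, E-value and score are kept.
    """
    hits = []
    for lineno, cols in _tblout_rows(path, 6):
        try:
            hits.append(
                DomainHit(
                    query_id=cols[2],
                    domain_accession=cols[1],
                    evalue=float(cols[4]),
                    score=float(cols[5]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"unparseable numeric field: {exc}", path=path, line=lineno)
    return hits


def read_cmscan(path) -> list[CmHit]:
    """Read Infernal cmscan ``--tblout`` output (18-column format).

    Columns: target name, target accession (Rfam family), query name,
    query accession, mdl, mdl from/to, seq from/to, strand, trunc, pass,
    gc, bias, score (15), E-value (16), inc, description.
    """
    hits = []
    for lineno, cols in _tblout_rows(path, 16):
        try:
            hits.append(
                CmHit(
                    query_id=cols[2],
                    model_accession=cols[1],
                    score=float(cols[14]),
                    evalue=float(cols[15]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"unparseable numeric field: {exc}", path=path, line=lineno)
    return hits


# ---------------------------------------------------------------------------
# expression table


def read_expression(path) -> list[ExpressionRecord]:
    """Read a two-plus-column (transcript_id, FPKM) table.

    An RSEM-style header row is detected by a field named ``FPKM`` and
    used to locate the column; otherwise column 2 is taken.
    """
    records = []
    fpkm_col = 1
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            upper = [c.upper() for c in cols]
            if lineno == 1 and "FPKM" in upper:
                fpkm_col = upper.index("FPKM")
                continue
            if len(cols) <= fpkm_col:
                raise FormatError(
                    f"expected >= {fpkm_col + 1} columns", path=path, line=lineno
                )
            try:
                fpkm = float(cols[fpkm_col])
            except ValueError as exc:
                raise FormatError(f"unparseable FPKM: {exc}", path=path, line=lineno)
            if fpkm < 0:
                raise FormatError("negative FPKM", path=path, line=lineno)
            records.append(ExpressionRecord(transcript_id=cols[0], fpkm=fpkm))
    return records


# ---------------------------------------------------------------------------
# GFF3 gene features

_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff3_genes(path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneModel]:
    """Read gene features from a GFF3 file and assign per-chromosome ranks.

    Genes of each chromosome are sorted by ascending start coordinate
    (ties broken by gene_id, lexicographically) and numbered 0..n-1;
    this rank is the order index all duplication logic works on.
    """
    raw: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError("expected 9 GFF3 columns", path=path, line=lineno)
            if cols[2] not in feature_types:
                continue
            m = _GFF_ID_RE.search(cols[8])
            if not m:
                raise FormatError(
                    f"{cols[2]} feature without ID attribute", path=path, line=lineno
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"unparseable coordinate: {exc}", path=path, line=lineno)
            if start > end:
                raise FormatError(f"start {start} > end {end}", path=path, line=lineno)
            raw.append(
                GeneModel(
                    gene_id=m.group(1),
                    chromosome=cols[0],
                    start=start,
                    end=end,
                    strand=cols[6] if cols[6] in "+-." else ".",
                )
            )
    return assign_ranks(raw)


def assign_ranks(genes: list[GeneModel]) -> list[GeneModel]:
    """Return genes with rank = order index along each chromosome."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chromosome].append(g)
    out: list[GeneModel] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(ordered):
            out.append(
                GeneModel(
                    gene_id=g.gene_id,
                    chromosome=g.chromosome,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    rank=rank,
                )
            )
    return out


# ---------------------------------------------------------------------------
# RNAfold output

_MFE_RE = re.compile(r"^([.()]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def read_rnafold(path) -> list[FoldResult]:
    """Read RNAfold plain-text output blocks.

    Each block is ``>id`` / sequence / ``dot-bracket ( mfe )``; the
    header line is optional (ids then default to ``seq_<n>``). The
    dot-bracket must be balanced and, when a sequence line is present,
    of equal length.
    """
    results: list[FoldResult] = []
    pending_id: str | None = None
    pending_seq: str | None = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                pending_id = line[1:].split()[0]
                pending_seq = None
                continue
            m = _MFE_RE.match(line)
            if m:
                db, mfe = m.group(1), float(m.group(2))
                if db.count("(") != db.count(")"):
                    raise FormatError("unbalanced dot-bracket", path=path, line=lineno)
                if pending_seq is not None and len(db) != len(pending_seq):
                    raise FormatError(
                        "dot-bracket length differs from sequence length",
                        path=path,
                        line=lineno,
                    )
                rid = pending_id if pending_id is not None else f"seq_{len(results) + 1}"
                results.append(FoldResult(id=rid, dot_bracket=db, mfe=mfe))
                pending_id = pending_seq = None
            else:
                if set(line.upper()) - _NUCLEOTIDES:
                    raise FormatError(
                        f"unrecognized line in RNAfold output: '{line[:40]}'",
                        path=path,
                        line=lineno,
                    )
                pending_seq = line.upper()
    if pending_seq is not None or pending_id is not None:
        raise FormatError("truncated final RNAfold block", path=path)
    return results


# ---------------------------------------------------------------------------
# CD-HIT .clstr

_CLSTR_HEADER_RE = re.compile(r"^>Cluster\s+(\d+)")
_CLSTR_MEMBER_RE = re.compile(r"^\d+\s+\d+(?:nt|aa),\s+>(.+?)\.\.\.\s+(.*)$")


def read_clstr(path) -> list[ClusterAssignment]:
    """Read a CD-HIT ``.clstr`` file; '*' marks a cluster's representative."""
    clusters: list[ClusterAssignment] = []
    cid: int | None = None
    members: list[str] = []
    rep: str | None = None

    def _flush(lineno):
        nonlocal cid, members, rep
        if cid is None:
            return
        if not members:
            raise FormatError(f"cluster {cid} has no members", path=path, line=lineno)
        if rep is None:
            raise FormatError(
                f"cluster {cid} has no '*' representative", path=path, line=lineno
            )
        clusters.append(
            ClusterAssignment(cluster_id=cid, member_ids=tuple(members), representative_id=rep)
        )
        members, rep = [], None

    with _open_text(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            h = _CLSTR_HEADER_RE.match(line)
            if h:
                _flush(lineno)
                cid = int(h.group(1))
                continue
            m = _CLSTR_MEMBER_RE.match(line)
            if not m:
                raise FormatError(f"unrecognized .clstr line: '{line[:40]}'", path=path, line=lineno)
            members.append(m.group(1))
            if m.group(2).strip() == "*":
                rep = m.group(1)
        _flush(lineno)
    seen: set[str] = set()
    for c in clusters:
        overlap = seen.intersection(c.member_ids)
        if overlap:
            raise FormatError(f"ids in multiple clusters: {sorted(overlap)}", path=path)
        seen.update(c.member_ids)
    return clusters


# ---------------------------------------------------------------------------
# pfam2go

_PFAM2GO_RE = re.compile(
    r"^Pfam:(?P<acc>\S+)\s+\S+\s+>\s+GO:.*?\s*;\s*(?P<go>GO:\d{7})\s*$"
)


def read_pfam2go(path) -> dict[str, list[tuple[str, str]]]:
    """Read a Pfam → GO mapping into ``{accession: [(go_id, go_class), ...]}``.

    Two dialects are accepted: a three-column TSV
    ``accession <TAB> GO:id <TAB> go_class`` (the form the synthetic
    bundle writes, carrying the ontology root each term belongs to), and
    the GO project's standard ``Pfam:PFxxxxx name > GO:desc ; GO:nnnnnnn``
    lines, for which the class is recorded as ``unknown``.
    """
    mapping: dict[str, list[tuple[str, str]]] = defaultdict(list)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            if "\t" in line:
                cols = line.split("\t")
                if len(cols) < 3:
                    raise FormatError("expected 3 TSV columns", path=path, line=lineno)
                acc, go_id, go_class = cols[0], cols[1], cols[2]
                if not go_id.startswith("GO:"):
                    raise FormatError(f"bad GO id '{go_id}'", path=path, line=lineno)
                mapping[acc].append((go_id, go_class))
                continue
            m = _PFAM2GO_RE.match(line)
            if not m:
                raise FormatError(f"unrecognized pfam2go line: '{line[:50]}'", path=path, line=lineno)
            # strip any trailing .NN version from the accession
            acc = m.group("acc").split(".")[0]
            mapping[acc].append((m.group("go"), "unknown"))
    return dict(mapping)
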