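"""Readers and writers for the external formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals; BLAST
tabular input (1-based inclusive, possibly reverse-strand) is normalised on
read.  Percent identity is held as a fraction in [0, 1].  Emitted BED is
0-based half-open; emitted tables with positions are 1-based and labelled.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ContigRecord",
    "AlignmentRecord",
    "CoverageTrack",
    "SnvRecord",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_alignments",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_vcf_snvs",
    "write_bed",
    "read_bed",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig (sequence optional for length-only workflows)."""

    contig_id: str
    sequence: str | None
    length: int
    source_tech: str = "short_read"  # {"long_read", "short_read"}
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.contig_id}: length {self.length} != |sequence| {len(self.sequence)}"
            )
        if self.source_tech not in ("long_read", "short_read"):
            raise ValueError(f"unknown source_tech {self.source_tech!r}")


@dataclass(frozen=True)
class AlignmentRecord:
    """A pairwise local alignment block, 0-based half-open on both sequences."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    n_matches: int
    aln_len: int
    pct_identity: float  # fraction in [0, 1]
    query_len: int
    target_len: int

    def __post_init__(self) -> None:
        for s, e, n, lab in (
            (self.query_start, self.query_end, self.query_len, "query"),
            (self.target_start, self.target_end, self.target_len, "target"),
        ):
            if not (0 <= s < e <= n):
                raise ValueError(
                    f"{self.query_id}->{self.target_id}: bad {lab} interval [{s},{e}) on length {n}"
                )
        if not 0.0 <= self.pct_identity <= 1.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0,1]")


@dataclass
class CoverageTrack:
    """Per-base read depth along one contig; index 0 is the first base."""

    contig_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if (self.depth < 0).any():
            raise ValueError(f"{self.contig_id}: negative depth")

    def __len__(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class SnvRecord:
    """A single-nucleotide variant site with per-allele read counts."""

    contig_id: str
    pos: int  # 0-based
    ref_allele: str
    allele_counts: dict[str, int]
    qual: float

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")
        if any(c < 0 for c in self.allele_counts.values()):
            raise ValueError("allele counts must be >= 0")

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, source_tech: str = "short_read") -> list[ContigRecord]:
    """Read a FASTA file into :class:`ContigRecord` objects.

    Sequences are uppercased; a duplicated header id raises
    :class:`ParseError`.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate contig id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            records.append(
                ContigRecord(rec.id, seq, len(seq), source_tech=source_tech)
            )
    return records


def write_fasta(contigs: Iterable[ContigRecord], path: str | Path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs
    ]
    if any(r.seq is None for r in recs):
        raise ValueError("cannot write contigs without sequence")
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Alignments (PAF / BLAST outfmt 6)

_BLAST6_NCOL = 12
_PAF_MIN_NCOL = 12


def _parse_blast6_line(fields: list[str], lineno: int, path, query_lens, target_lens) -> AlignmentRecord:
    (qseqid, sseqid, pident, length, _mm, _go, qstart, qend, sstart, send, _ev, _bs) = fields[:12]
    qs, qe, ss, se = int(qstart), int(qend), int(sstart), int(send)
    # 1-based inclusive -> 0-based half-open; reverse-strand target normalised
    if qs > qe:
        raise ParseError(f"{path}:{lineno}: reversed query interval unsupported in blast6")
    if ss > se:
        ss, se = se, ss
    aln_len = int(length)
    ident = float(pident) / 100.0
    n_matches = int(round(ident * aln_len))
    qlen = query_lens.get(qseqid) if query_lens else None
    tlen = target_lens.get(sseqid) if target_lens else None
    return AlignmentRecord(
        query_id=qseqid,
        target_id=sseqid,
        query_start=qs - 1,
        query_end=qe,
        target_start=ss - 1,
        target_end=se,
        n_matches=n_matches,
        aln_len=aln_len,
        pct_identity=ident,
        query_len=qlen if qlen is not None else qe,
        target_len=tlen if tlen is not None else se,
    )


def _parse_paf_line(fields: list[str], lineno: int, path) -> AlignmentRecord:
    (qname, qlen, qstart, qend, _strand, tname, tlen, tstart, tend, nmatch, alnlen) = (
        fields[0],
        int(fields[1]),
        int(fields[2]),
        int(fields[3]),
        fields[4],
        fields[5],
        int(fields[6]),
        int(fields[7]),
        int(fields[8]),
        int(fields[9]),
        int(fields[10]),
    )
    return AlignmentRecord(
        query_id=qname,
        target_id=tname,
        query_start=qstart,
        query_end=qend,
        target_start=tstart,
        target_end=tend,
        n_matches=nmatch,
        aln_len=alnlen,
        pct_identity=nmatch / alnlen if alnlen else 0.0,
        query_len=qlen,
        target_len=tlen,
    )


def read_alignments(
    path: str | Path,
    dialect: str,
    query_lens: dict[str, int] | None = None,
    target_lens: dict[str, int] | None = None,
) -> list[AlignmentRecord]:
    """Read pairwise alignments from PAF or BLAST tabular (outfmt 6).

    Parameters
    ----------
    dialect:
        ``"paf"`` (12+ columns, already 0-based half-open) or ``"blast6"``
        (qseqid sseqid pident length mismatch gapopen qstart qend sstart
        send evalue bitscore; 1-based inclusive, converted on read).
    query_lens, target_lens:
        Sequence lengths by id.  BLAST-6 rows do not carry lengths, so these
        are needed whenever downstream coverage fractions matter; without
        them the alignment end coordinate is used as a lower bound.
    """
    if dialect not in ("paf", "blast6"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[AlignmentRecord] = []
    min_cols = _PAF_MIN_NCOL if dialect == "paf" else _BLAST6_NCOL
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            if dialect == "paf":
                records.append(_parse_paf_line(fields, lineno, path))
            else:
                records.append(
                    _parse_blast6_line(fields, lineno, path, query_lens, target_lens)
                )
    return records


# ---------------------------------------------------------------------------
# Per-base depth (bedtools genomecov -d dialect)


def read_depth_tsv(path: str | Path) -> list[CoverageTrack]:
    """Read a 3-column per-base depth table (contig, 1-based pos, depth).

    Positions must be contiguous (1..L) within each contig; a gap, repeat or
    out-of-order position raises :class:`ParseError`.  Contigs may follow one
    another in any order but must not interleave.
    """
    tracks: list[CoverageTrack] = []
    done: set[str] = set()
    current: str | None = None
    depths: list[int] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            contig, pos_s, depth_s = fields
            pos, depth = int(pos_s), int(depth_s)
            if contig != current:
                if current is not None:
                    tracks.append(CoverageTrack(current, np.array(depths)))
                    done.add(current)
                if contig in done:
                    raise ParseError(f"{path}:{lineno}: contig {contig!r} interleaved")
                current, depths = contig, []
            if pos != len(depths) + 1:
                raise ParseError(
                    f"{path}:{lineno}: position {pos} breaks 1..L contiguity for {contig!r}"
                )
            depths.append(depth)
    if current is not None:
        tracks.append(CoverageTrack(current, np.array(depths)))
    return tracks


def write_depth_tsv(tracks: Iterable[CoverageTrack], path: str | Path) -> None:
    """Write per-base depth in the 3-column 1-based dialect read_depth_tsv expects."""
    with open(path, "w") as handle:
        for track in tracks:
            for i, d in enumerate(track.depth, 1):
                handle.write(f"{track.contig_id}\t{i}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# VCF SNVs


def read_vcf_snvs(path: str | Path) -> tuple[list[SnvRecord], int]:
    """Read SNV sites from a VCF 4.2 file.

    Returns ``(records, n_skipped_indels)``.  Allele read counts come from
    the first sample's ``AD`` field (ref followed by each alt); sites without
    ``AD`` raise :class:`ParseError`.  Indel lines (any allele longer than
    one base, or symbolic) are skipped and counted.
    """
    records: list[SnvRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alleles = (rec.ref,) + tuple(rec.alts or ())
            if any(a is None or len(a) != 1 or a not in "ACGTN" for a in alleles):
                skipped += 1
                continue
            ad = None
            if rec.samples:
                sample = rec.samples[0]
                ad = sample.get("AD")
            if ad is None:
                info_ad = rec.info.get("AD") if "AD" in rec.info else None
                ad = info_ad
            if ad is None or any(a is None for a in ad):
                raise ParseError(
                    f"{path}: site {rec.chrom}:{rec.pos} lacks AD allele depths"
                )
            counts = {a: int(c) for a, c in zip(alleles, ad)}
            records.append(
                SnvRecord(
                    contig_id=rec.chrom,
                    pos=rec.pos - 1,
                    ref_allele=rec.ref,
                    allele_counts=counts,
                    qual=float(rec.qual if rec.qual is not None else 0.0),
                )
            )
    if skipped:
        logger.info("read_vcf_snvs: skipped %d indel/non-SNV lines", skipped)
    return records, skipped


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write BED3/BED6 rows: tuples of (chrom, start, end[, name, score, strand])."""
    with open(path, "w") as handle:
        for row in intervals:
            handle.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    """Read BED rows back as tuples with integer start/end."""
    rows: list[tuple] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            fields[1], fields[2] = int(fields[1]), int(fields[2])  # type: ignore[call-overload]
            rows.append(tuple(fields))
    return rows
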