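"""Readers and writers for the on-disk formats the pipeline touches.

Formats
-------
* FASTA / FASTQ (Sanger quality encoding) via Biopython.
* 12-column whitespace-delimited hit tables (the conventional tabular
  alignment dialect: qid, sid, pident, length, mismatch, gapopen, qstart,
  qend, sstart, send, evalue, bitscore). The e-value column is parsed and
  preserved but never used downstream.
* 2-column lineage TSV: reference_id, semicolon-joined ranked taxa.
* OTU tables as TSV with lineage-string rows and sample columns.

Coordinate conventions: everything on disk is 1-based inclusive, with a
subject start > end encoding a minus-strand alignment; internal trimming
coordinates elsewhere in the package are 0-based half-open.  Conversion
happens only here, at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file failed validation against its declared format."""


@dataclass(frozen=True)
class Read:
    """One sequencing read: uppercase DNA over {A,C,G,T,N}, optional quality."""

    read_id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"read {self.read_id!r}: invalid bases {sorted(bad)}"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular alignment file.

    ``percent_identity`` is stored as printed (0-100 scale).  Coordinates are
    1-based inclusive; ``subject_start > subject_end`` encodes a minus-strand
    alignment, surfaced via :attr:`strand`.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    raw_score: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.query_start < 1 or self.query_end < self.query_start:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: bad query "
                f"coordinates {self.query_start}..{self.query_end}"
            )
        if min(self.subject_start, self.subject_end) < 1:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: bad subject "
                f"coordinates {self.subject_start}..{self.subject_end}"
            )

    @property
    def strand(self) -> str:
        return "minus" if self.subject_start > self.subject_end else "plus"


@dataclass(frozen=True)
class LineageRecord:
    """A reference sequence's ranked taxon path, root-most rank first."""

    reference_id: str
    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise FormatError(f"lineage for {self.reference_id!r} is empty")
        if any(not r for r in self.ranks):
            raise FormatError(
                f"lineage for {self.reference_id!r} has an empty rank"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fastx(path: str | Path, format: str = "fasta") -> Iterator[Read]:
    """Stream reads from a FASTA or FASTQ file.

    Lowercase sequence is uppercased.  An empty file yields an empty stream;
    a malformed record raises :class:`FormatError` naming the offending
    record.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    try:
        for rec in SeqIO.parse(str(path), format):
            qual = None
            if format == "fastq":
                qual = tuple(rec.letter_annotations["phred_quality"])
            yield Read(rec.id, str(rec.seq).upper(), qual)
    except ValueError as exc:  # Biopython's parse error
        raise FormatError(f"{path}: {exc}") from exc


def write_fastx(path: str | Path, reads: Iterable[Read], format: str = "fasta") -> int:
    """Write reads to FASTA/FASTQ; returns the number of records written."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if format == "fastq":
            qual = r.quality if r.quality is not None else (30,) * len(r)
            rec.letter_annotations["phred_quality"] = list(qual)
        records.append(rec)
    return SeqIO.write(records, str(Path(path)), format)


# ---------------------------------------------------------------------------
# 12-column hit tables


_HIT_COLUMNS = 12


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a whitespace-delimited 12-column tabular alignment file."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        query_start=int(parts[6]),
                        query_end=int(parts[7]),
                        subject_start=int(parts[8]),
                        subject_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def _fmt_float(x: float) -> str:
    if math.isfinite(x) and x == int(x) and abs(x) < 1e15:
        return f"{x:.1f}"
    return repr(x)


def write_hit_table(path: str | Path, hits: Iterable[HitRecord]) -> int:
    n = 0
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.3f}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.query_start),
                        str(h.query_end),
                        str(h.subject_start),
                        str(h.subject_end),
                        repr(h.evalue),
                        _fmt_float(h.bitscore),
                    ]
                )
                + "\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# Lineages


def read_lineages(path: str | Path) -> dict[str, LineageRecord]:
    """Read a two-column TSV mapping reference_id -> semicolon-joined lineage."""
    out: dict[str, LineageRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            ref_id, lineage = parts
            if ref_id in out:
                raise FormatError(
                    f"{path}:{lineno}: duplicate reference id {ref_id!r}"
                )
            ranks = tuple(t.strip() for t in lineage.split(";"))
            if not lineage.strip() or any(not r for r in ranks):
                raise FormatError(
                    f"{path}:{lineno}: empty lineage component for {ref_id!r}"
                )
            out[ref_id] = LineageRecord(ref_id, ranks)
    return out


def write_lineages(path: str | Path, lineages: dict[str, LineageRecord]) -> int:
    with open(path, "w") as fh:
        for ref_id, rec in lineages.items():
            fh.write(f"{ref_id}\t{';'.join(rec.ranks)}\n")
    return len(lineages)
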