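"""Alignment-based demultiplexing of pooled tagged nanopore amplicon reads.

Each read is assigned to a library by locating tagged primers near both
ends, requiring 90%-or-more primer coverage, agreement of the two ends on
one library, and the marker-specific full-read length window (16S
1200-1700 bp, ITS 600-900 bp by default).  The insert between the two
primer alignments is trimmed out and reported in insert-forward
orientation.

Candidate primers per end zone are screened with a bounded-edit-distance
filter (edlib) and the survivors rescored with the exact Smith-Waterman
routine in :mod:`minitag.align`, so reported hits carry exact local
alignment scores and coordinates.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib

from .align import bitscore, revcomp, smith_waterman
from .io_formats import Read
from .tag_design import LibraryPlan, TaggedPrimer

DEFAULT_WINDOWS = {"16S": (1200, 1700), "ITS": (600, 900)}
DEFAULT_MIN_COVERAGE = 0.90
DEFAULT_END_ZONE = 150
DEFAULT_SCORE_FLOOR = 18.0
#: a chosen end hit must begin (head) or end (tail) within this many bases
#: of the read terminus — amplicon reads are primer-terminal, and this is
#: what separates a round-1 read from the round-1 primer nested inside a
#: round-2 read (whose hit sits ~26 bases in)
DEFAULT_TERMINAL_SLACK = 12

STATUSES = (
    "assigned",
    "no_forward_hit",
    "no_reverse_hit",
    "barcode_mismatch",
    "length_fail",
    "coverage_fail",
)


class DemuxConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerHit:
    """One local alignment of a tagged primer against a read region.

    Coordinates are 0-based half-open on the plus strand of the read,
    regardless of the hit strand.
    """

    primer_name: str
    read_id: str
    strand: str  # plus | minus
    read_start: int
    read_end: int
    primer_coverage: float
    raw_score: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0 <= self.read_start < self.read_end):
            raise ValueError("bad hit coordinates")
        if not (0 < self.primer_coverage <= 1):
            raise ValueError("primer_coverage must be in (0, 1]")


@dataclass(frozen=True)
class DemuxRecord:
    """Per-read demultiplexing verdict."""

    read_id: str
    status: str
    library_id: str | None = None
    marker: str | None = None
    trimmed_sequence: str | None = None
    fwd_hit: PrimerHit | None = None
    rev_hit: PrimerHit | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        assigned = self.status == "assigned"
        if assigned != (
            self.library_id is not None and self.trimmed_sequence is not None
        ):
            raise ValueError("assigned iff library and trimmed sequence set")


def filter_hits(
    hits: Iterable[PrimerHit], min_coverage: float = DEFAULT_MIN_COVERAGE
) -> list[PrimerHit]:
    """Keep hits covering at least ``min_coverage`` of the primer (inclusive)."""
    return [h for h in hits if h.primer_coverage >= min_coverage]


def validate_windows(windows: dict[str, tuple[int, int]]) -> None:
    items = list(windows.items())
    for marker, (lo, hi) in items:
        if lo > hi or lo < 1:
            raise DemuxConfigError(f"bad length window for {marker}: {lo}-{hi}")
    for (m1, (a1, b1)), (m2, (a2, b2)) in zip(items, items[1:]):
        if max(a1, a2) <= min(b1, b2):
            raise DemuxConfigError(
                f"length windows for {m1} and {m2} overlap"
            )


# ---------------------------------------------------------------------------
# Primer alignment


def align_primer(
    primer: TaggedPrimer | str,
    read: Read,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> list[PrimerHit]:
    """All non-overlapping local alignments of a tagged primer on both strands.

    Exact full Smith-Waterman (no seeding).  Hits are reported in plus-strand
    read coordinates; ``primer_coverage`` is aligned primer bases over primer
    length.  No hit above the score floor yields an empty list.
    """
    from .align import local_align_all

    name = primer.name if isinstance(primer, TaggedPrimer) else "primer"
    seq = (
        primer.full_sequence if isinstance(primer, TaggedPrimer) else primer
    )
    plen = len(seq)
    L = len(read)
    hits: list[PrimerHit] = []
    for strand, target in (("plus", read.sequence), ("minus", revcomp(read.sequence))):
        for aln in local_align_all(seq, target, score_floor):
            if strand == "plus":
                start, end = aln.target_start, aln.target_end
            else:
                start, end = L - aln.target_end, L - aln.target_start
            hits.append(
                PrimerHit(
                    primer_name=name,
                    read_id=read.read_id,
                    strand=strand,
                    read_start=start,
                    read_end=end,
                    primer_coverage=aln.query_aligned / plen,
                    raw_score=aln.score,
                    bitscore=bitscore(aln.score),
                )
            )
    hits.sort(key=lambda h: (-h.raw_score, -h.primer_coverage, h.primer_name))
    return hits


# ---------------------------------------------------------------------------
# Fast candidate screening for pools


#: IUPAC degeneracies passed to edlib so codes like M match their bases.
_EDLIB_EQUALITIES = [
    ("M", "A"), ("M", "C"), ("R", "A"), ("R", "G"),
    ("Y", "C"), ("Y", "T"), ("W", "A"), ("W", "T"),
    ("S", "C"), ("S", "G"), ("K", "G"), ("K", "T"),
]


class _PrimerIndex:
    """Primer lookup plus the hierarchical candidate screen.

    Screening proceeds core-first: the four marker core primers (and their
    reverse complements) are located in each end zone with bounded-edit
    edlib searches; a core hit fixes marker, orientation and strand, and
    the adjacent tag region is then ranked against every library's tag
    block by anchored edit distance.  Only the best few tag candidates are
    rescored with exact Smith-Waterman, which is what produces the reported
    hits — so scores, coordinates and coverage are exact while the work per
    read stays small.  Tag sets with pairwise edit distance >= 8 make the
    distance ranking and the score ranking agree by a wide margin.
    """

    #: max core edits tolerated in the screen (nanopore-like 9% error puts
    #: ~2 expected edits on a 20-mer core; 6 leaves generous headroom)
    core_k = 6
    #: rescore candidates within this tag-distance margin of the best
    margin = 3
    #: never rescore more than this many candidates per core hit
    top_k = 5
    #: candidates with tag distance above 0.4 * tag length are discarded
    tag_k_frac = 0.4
    #: extra target bases allowed beyond the tag block (indel slack)
    slack = 6

    def __init__(self, plans: Sequence[LibraryPlan]):
        self.plans = list(plans)
        if not self.plans:
            raise DemuxConfigError("empty primer sheet")
        self.primers: dict[str, TaggedPrimer] = {}
        self.library_of_primer: dict[str, LibraryPlan] = {}
        self.groups: dict[tuple[str, str], list[TaggedPrimer]] = {}
        for plan in self.plans:
            for p in (plan.forward_primer, plan.reverse_primer):
                if p.name in self.primers:
                    raise DemuxConfigError(f"duplicate primer name {p.name}")
                self.primers[p.name] = p
                self.library_of_primer[p.name] = plan
                self.groups.setdefault((p.marker, p.orientation), []).append(p)
        from .tag_design import PRIMER_CORES

        self.core_queries = []
        for (marker, orient), core in PRIMER_CORES.items():
            if (marker, orient) in self.groups:
                self.core_queries.append((marker, orient, "plus", core))
                self.core_queries.append((marker, orient, "minus", revcomp(core)))

    def screen_zone(self, zone: str) -> list[tuple[TaggedPrimer, str]]:
        out: list[tuple[TaggedPrimer, str]] = []
        seen: set[tuple[str, str]] = set()
        for marker, orient, strand, core_q in self.core_queries:
            res = edlib.align(
                core_q, zone, mode="HW", task="locations", k=self.core_k,
                additionalEqualities=_EDLIB_EQUALITIES,
            )
            if res["editDistance"] == -1:
                continue
            core_start, core_end = res["locations"][0]  # end inclusive
            scored: list[tuple[int, TaggedPrimer]] = []
            for p in self.groups[(marker, orient)]:
                tags = p.tag2 + p.tag1
                k_tag = math.ceil(self.tag_k_frac * len(tags))
                if strand == "plus":
                    # tags precede the core; anchor at the core boundary by
                    # reversing both strings (SHW: start-anchored, free end)
                    region = zone[
                        max(0, core_start - len(tags) - self.slack) : core_start
                    ]
                    q, t = tags[::-1], region[::-1]
                else:
                    # rc(primer) = rc(core) + rc(tag1+tag2 block)
                    region = zone[
                        core_end + 1 : core_end + 1 + len(tags) + self.slack
                    ]
                    q, t = revcomp(tags), region
                if not t:
                    continue
                d = edlib.align(q, t, mode="SHW", task="distance", k=k_tag)[
                    "editDistance"
                ]
                if d != -1:
                    scored.append((d, p))
            scored.sort(key=lambda x: (x[0], x[1].name))
            if not scored:
                continue
            best_d = scored[0][0]
            for d, p in scored[: self.top_k]:
                if d > best_d + self.margin:
                    break
                if (p.name, strand) not in seen:
                    seen.add((p.name, strand))
                    out.append((p, strand))
        return out


def _zone_hits(
    index: _PrimerIndex, read: Read, zone_start: int, zone_end: int,
    score_floor: float,
) -> list[PrimerHit]:
    """Exact primer hits within one end zone of a read."""
    zone = read.sequence[zone_start:zone_end]
    hits: list[PrimerHit] = []
    for primer, strand in index.screen_zone(zone):
        seq = primer.full_sequence if strand == "plus" else revcomp(
            primer.full_sequence
        )
        aln = smith_waterman(seq, zone)
        if aln is None or aln.score < score_floor:
            continue
        start = zone_start + aln.target_start
        end = zone_start + aln.target_end
        if strand == "minus":
            # query was the reverse complement of the primer: coverage and
            # coordinates are already in plus-strand read space
            pass
        hits.append(
            PrimerHit(
                primer_name=primer.name,
                read_id=read.read_id,
                strand=strand,
                read_start=start,
                read_end=end,
                primer_coverage=aln.query_aligned / len(primer),
                raw_score=aln.score,
                bitscore=bitscore(aln.score),
            )
        )
    return hits


def _top_hit(hits: list[PrimerHit]) -> PrimerHit | None:
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.raw_score, -h.primer_coverage, h.primer_name))


def classify_read(
    read: Read,
    plans: Sequence[LibraryPlan] | _PrimerIndex,
    length_windows: dict[str, tuple[int, int]] | None = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    end_zone: int = DEFAULT_END_ZONE,
    score_floor: float = DEFAULT_SCORE_FLOOR,
    terminal_slack: int = DEFAULT_TERMINAL_SLACK,
) -> DemuxRecord:
    """Classify one read against the tagged primer set.

    Procedure: (1) reads whose length misses every marker window are
    length_fail; (2) the top coverage-passing hit in the first ``end_zone``
    bases and in the last ``end_zone`` bases are selected, considering only
    hits anchored within ``terminal_slack`` of the read terminus (the
    barcoded primers must sit at the ends); (3) the two hits must name the
    forward and reverse primer of one library on opposite strands, else
    barcode_mismatch; the winning library's marker window is re-checked;
    (4) the insert strictly between the primer alignments is trimmed and
    oriented insert-forward.
    """
    windows = length_windows or DEFAULT_WINDOWS
    validate_windows(windows)
    index = plans if isinstance(plans, _PrimerIndex) else _PrimerIndex(plans)
    L = len(read)

    if not any(lo <= L <= hi for lo, hi in windows.values()):
        return DemuxRecord(read.read_id, "length_fail")

    head_end = min(end_zone, L)
    tail_start = max(L - end_zone, head_end)
    head_raw = _zone_hits(index, read, 0, head_end, score_floor)
    tail_raw = (
        _zone_hits(index, read, tail_start, L, score_floor)
        if tail_start < L
        else []
    )
    head_raw = [h for h in head_raw if h.read_start <= terminal_slack]
    tail_raw = [h for h in tail_raw if h.read_end >= L - terminal_slack]

    head = filter_hits(head_raw, min_coverage)
    tail = filter_hits(tail_raw, min_coverage)
    h_top, t_top = _top_hit(head), _top_hit(tail)

    if h_top is None and t_top is None:
        if head_raw or tail_raw:
            return DemuxRecord(read.read_id, "coverage_fail")
        return DemuxRecord(read.read_id, "no_forward_hit")
    if h_top is None or t_top is None:
        present = h_top or t_top
        primer = index.primers[present.primer_name]
        # decide which end is missing after strand normalisation: a plus
        # strand forward primer (or minus-strand reverse) puts the insert's
        # 5' end at the hit, so the reverse side is the absent one
        fwd_present = (primer.orientation == "forward") == (
            present.strand == "plus"
        )
        missing_raw = tail_raw if present is h_top else head_raw
        if missing_raw:
            return DemuxRecord(read.read_id, "coverage_fail")
        return DemuxRecord(
            read.read_id,
            "no_reverse_hit" if fwd_present else "no_forward_hit",
        )

    # ambiguity guard: if a coverage-failing hit outscores the chosen hit at
    # the same end and names a different library, the end's best evidence
    # failed the coverage rule — discard rather than fall back.  A nested
    # round-2 primer clipped below 90% coverage on a round-2 read is the
    # canonical case; on a true round-1 read the round-2 primer aligns only
    # its round-1 suffix and cannot strictly outscore, so the guard never
    # fires there.
    for chosen, raw in ((h_top, head_raw), (t_top, tail_raw)):
        for h in raw:
            if h.raw_score > chosen.raw_score and (
                index.library_of_primer[h.primer_name].library_id
                != index.library_of_primer[chosen.primer_name].library_id
            ):
                return DemuxRecord(read.read_id, "coverage_fail")

    p_head = index.primers[h_top.primer_name]
    p_tail = index.primers[t_top.primer_name]
    lib_head = index.library_of_primer[h_top.primer_name]
    lib_tail = index.library_of_primer[t_top.primer_name]

    same_library = lib_head.library_id == lib_tail.library_id
    opposite_orient = {p_head.orientation, p_tail.orientation} == {
        "forward",
        "reverse",
    }
    opposite_strand = {h_top.strand, t_top.strand} == {"plus", "minus"}
    if not (same_library and opposite_orient and opposite_strand):
        return DemuxRecord(read.read_id, "barcode_mismatch")

    # read layout: the head-zone hit precedes the tail-zone hit; the read is
    # flipped (insert on minus strand) when the plus-strand hit is a reverse
    # primer
    plus_hit = h_top if h_top.strand == "plus" else t_top
    plus_primer = index.primers[plus_hit.primer_name]
    flipped = plus_primer.orientation == "reverse"
    if h_top.read_end > t_top.read_start:
        return DemuxRecord(read.read_id, "barcode_mismatch")

    marker = lib_head.marker
    lo, hi = windows[marker]
    if not lo <= L <= hi:
        return DemuxRecord(read.read_id, "length_fail")

    insert = read.sequence[h_top.read_end : t_top.read_start]
    if flipped:
        insert = revcomp(insert)
    if not insert:
        return DemuxRecord(read.read_id, "barcode_mismatch")
    fwd_hit = t_top if flipped else h_top
    rev_hit = h_top if flipped else t_top
    return DemuxRecord(
        read_id=read.read_id,
        status="assigned",
        library_id=lib_head.library_id,
        marker=marker,
        trimmed_sequence=insert,
        fwd_hit=fwd_hit,
        rev_hit=rev_hit,
    )


# ---------------------------------------------------------------------------
# Pool-level driver


@dataclass
class DemuxSummary:
    status_counts: dict[str, int]
    per_library: dict[str, int]
    n_reads: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_reads": self.n_reads,
                "status_counts": self.status_counts,
                "per_library_N": self.per_library,
            },
            indent=2,
            sort_keys=True,
        )


def demux_pool(
    reads: Iterable[Read],
    plans: Sequence[LibraryPlan],
    length_windows: dict[str, tuple[int, int]] | None = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    end_zone: int = DEFAULT_END_ZONE,
    score_floor: float = DEFAULT_SCORE_FLOOR,
    terminal_slack: int = DEFAULT_TERMINAL_SLACK,
    out_dir: str | Path | None = None,
) -> tuple[list[DemuxRecord], DemuxSummary]:
    """Demultiplex a pooled read set.

    Every read lands in exactly one status category; per-library assigned
    counts are the N column of the per-sample statistics.  When ``out_dir``
    is given, per-library FASTA files of trimmed inserts, a demux TSV and a
    JSON summary are written there.
    """
    windows = length_windows or DEFAULT_WINDOWS
    validate_windows(windows)
    index = _PrimerIndex(plans)
    records: list[DemuxRecord] = []
    status_counts: Counter[str] = Counter()
    per_library: Counter[str] = Counter()
    n = 0
    for read in reads:
        n += 1
        rec = classify_read(
            read, index, windows, min_coverage, end_zone, score_floor,
            terminal_slack,
        )
        records.append(rec)
        status_counts[rec.status] += 1
        if rec.status == "assigned":
            per_library[rec.library_id] += 1
    if n == 0:
        raise DemuxConfigError("no input reads")
    summary = DemuxSummary(
        status_counts={s: status_counts.get(s, 0) for s in STATUSES},
        per_library={p.library_id: per_library.get(p.library_id, 0) for p in plans},
        n_reads=n,
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), records, summary)
    return records, summary


def _write_outputs(
    out_dir: Path, records: list[DemuxRecord], summary: DemuxSummary
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    handles: dict[str, list[str]] = {}
    for rec in records:
        if rec.status == "assigned":
            handles.setdefault(rec.library_id, []).append(
                f">{rec.read_id}\n{rec.trimmed_sequence}\n"
            )
    lib_dir = out_dir / "libraries"
    lib_dir.mkdir(exist_ok=True)
    for lib, chunks in handles.items():
        (lib_dir / f"{lib}.fasta").write_text("".join(chunks))
    with open(out_dir / "demux.tsv", "w") as fh:
        fh.write(
            "read_id\tstatus\tlibrary_id\tmarker\t"
            "fwd_start\tfwd_end\trev_start\trev_end\n"
        )
        for rec in records:
            fwd = rec.fwd_hit
            rev = rec.rev_hit
            fh.write(
                "\t".join(
                    [
                        rec.read_id,
                        rec.status,
                        rec.library_id or ".",
                        rec.marker or ".",
                        str(fwd.read_start) if fwd else ".",
                        str(fwd.read_end) if fwd else ".",
                        str(rev.read_start) if rev else ".",
                        str(rev.read_end) if rev else ".",
                    ]
                )
                + "\n"
            )
    (out_dir / "summary.json").write_text(summary.to_json())
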