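"""Taxonomy assignment by the thresholded lowest-common-ancestor rule.

For each demultiplexed read, candidate reference hits are taken from a
12-column tabular alignment table (produced by the bundled blastn wrapper
or any external tool emitting that dialect).  A read is assignable when its
top hit reaches 100 bits; the candidate set is every hit within 99.5% of
the top bitscore (both bounds inclusive, the relative rule mirroring a
``-t 0.995`` setting), and the assignment is the deepest lineage shared by
all candidates.  Each distinct assigned lineage is one taxon, later treated
as an OTU.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import HitRecord, LineageRecord, read_hit_table

DEFAULT_MIN_TOP_BITSCORE = 100.0
DEFAULT_RELATIVE_THRESHOLD = 0.995

Lineage = tuple[str, ...]

UNASSIGNED_NO_HIT = "no_hit"
UNASSIGNED_LOW_BITSCORE = "below_bitscore_floor"


class TaxonomyError(ValueError):
    pass


@dataclass(frozen=True)
class TaxAssignment:
    """LCA result for one read."""

    read_id: str
    assigned_lineage: Lineage  # may be empty = root
    top_bitscore: float
    n_candidates: int

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise TaxonomyError("n_candidates must be >= 1")

    @property
    def taxon(self) -> str:
        """The taxon label: the full lineage joined with semicolons."""
        return ";".join(self.assigned_lineage) if self.assigned_lineage else "root"


def candidate_set(
    hits_for_read: Sequence[HitRecord],
    min_top_bitscore: float = DEFAULT_MIN_TOP_BITSCORE,
    t: float = DEFAULT_RELATIVE_THRESHOLD,
) -> list[HitRecord]:
    """Hits within ``t`` of the top bitscore, empty if the top is sub-floor.

    Only the best hit per subject participates (multiple HSPs against one
    reference collapse to the highest-scoring one).
    """
    if not hits_for_read:
        return []
    best_per_subject: dict[str, HitRecord] = {}
    for h in hits_for_read:
        cur = best_per_subject.get(h.subject_id)
        if cur is None or h.bitscore > cur.bitscore:
            best_per_subject[h.subject_id] = h
    hits = sorted(
        best_per_subject.values(), key=lambda h: (-h.bitscore, h.subject_id)
    )
    top = hits[0].bitscore
    if top < min_top_bitscore:
        return []
    cutoff = t * top
    return [h for h in hits if h.bitscore >= cutoff]


def lca(lineages: Iterable[Lineage]) -> Lineage:
    """Deepest lineage that is a prefix of every input; () when none shared."""
    lineages = list(lineages)
    if not lineages:
        raise TaxonomyError("lca of empty set is undefined")
    first = lineages[0]
    depth = len(first)
    for lin in lineages[1:]:
        d = 0
        for a, b in zip(first, lin):
            if a != b:
                break
            d += 1
        depth = min(depth, d)
        if depth == 0:
            return ()
    return tuple(first[:depth])


def assign_read(
    read_id: str,
    hits: Sequence[HitRecord],
    lineage_map: Mapping[str, LineageRecord],
    min_top_bitscore: float = DEFAULT_MIN_TOP_BITSCORE,
    t: float = DEFAULT_RELATIVE_THRESHOLD,
) -> TaxAssignment | str:
    """Assignment for one read, or an unassigned-reason string."""
    if not hits:
        return UNASSIGNED_NO_HIT
    cands = candidate_set(hits, min_top_bitscore, t)
    if not cands:
        return UNASSIGNED_LOW_BITSCORE
    lineages = []
    for h in cands:
        rec = lineage_map.get(h.subject_id)
        if rec is None:
            raise TaxonomyError(
                f"hit for read {read_id!r} references unknown reference "
                f"id {h.subject_id!r}"
            )
        lineages.append(rec.ranks)
    return TaxAssignment(
        read_id=read_id,
        assigned_lineage=lca(lineages),
        top_bitscore=cands[0].bitscore,
        n_candidates=len(cands),
    )


def assign_all(
    hit_table: Sequence[HitRecord],
    lineage_map: Mapping[str, LineageRecord],
    read_ids: Sequence[str] | None = None,
    min_top_bitscore: float = DEFAULT_MIN_TOP_BITSCORE,
    t: float = DEFAULT_RELATIVE_THRESHOLD,
) -> tuple[list[TaxAssignment], dict[str, str]]:
    """LCA-assign every read in a hit table.

    ``read_ids``, when given, lists all reads that were searched, so reads
    with no hit at all are reported; otherwise only reads present in the
    table are considered.  Returns (assignments, unassigned read -> reason).
    """
    by_read: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hit_table:
        by_read[h.query_id].append(h)
    ids = list(read_ids) if read_ids is not None else list(by_read)
    assignments: list[TaxAssignment] = []
    unassigned: dict[str, str] = {}
    for rid in ids:
        result = assign_read(
            rid, by_read.get(rid, ()), lineage_map, min_top_bitscore, t
        )
        if isinstance(result, TaxAssignment):
            assignments.append(result)
        else:
            unassigned[rid] = result
    return assignments, unassigned


def write_assignments(
    path: str | Path,
    assignments: Sequence[TaxAssignment],
    unassigned: Mapping[str, str] | None = None,
    library_of_read: Mapping[str, str] | None = None,
) -> None:
    lib = library_of_read or {}
    with open(path, "w") as fh:
        fh.write(
            "read_id\tlibrary_id\tlineage\ttop_bitscore\tn_candidates\tstatus\n"
        )
        for a in assignments:
            fh.write(
                f"{a.read_id}\t{lib.get(a.read_id, '.')}\t{a.taxon}\t"
                f"{a.top_bitscore:g}\t{a.n_candidates}\tassigned\n"
            )
        for rid, reason in (unassigned or {}).items():
            fh.write(f"{rid}\t{lib.get(rid, '.')}\t.\t0\t0\t{reason}\n")


# ---------------------------------------------------------------------------
# blastn wrapper producing the 12-column hit table


def blast_available() -> bool:
    return shutil.which("blastn") is not None and shutil.which("makeblastdb") is not None


def blast_search(
    query_fasta: str | Path,
    reference_fasta: str | Path,
    out_table: str | Path | None = None,
    word_size: int | None = None,
    task: str = "megablast",
) -> list[HitRecord]:
    """Search reads against a reference set with blastn, 12-column output.

    Builds a temporary nucleotide database from ``reference_fasta`` and runs
    ``blastn -outfmt 6``; the resulting table parses into the package's
    :class:`HitRecord` dialect with blast's own bitscores.
    """
    if not blast_available():
        raise TaxonomyError("blastn/makeblastdb not found on PATH")
    query_fasta = Path(query_fasta)
    reference_fasta = Path(reference_fasta)
    with tempfile.TemporaryDirectory() as tmp:
        db = Path(tmp) / "refdb"
        subprocess.run(
            [
                "makeblastdb", "-in", str(reference_fasta),
                "-dbtype", "nucl", "-out", str(db),
            ],
            check=True,
            capture_output=True,
        )
        out = Path(out_table) if out_table else Path(tmp) / "hits.tsv"
        cmd = [
            "blastn", "-query", str(query_fasta), "-db", str(db),
            "-outfmt", "6", "-task", task, "-out", str(out),
        ]
        if word_size is not None:
            cmd += ["-word_size", str(word_size)]
        subprocess.run(cmd, check=True, capture_output=True)
        return read_hit_table(out)
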