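"""Synthetic references, communities, and tagged nanopore-like reads.

The simulator stands in for the unreleased sequencing run and the large
public marker databases, at toy scale and with full ground truth:

* references evolve along a random taxonomy tree, so taxa that share
  lineage also share sequence similarity;
* community profiles emulate the study's contrasts — untreated ("raw")
  soil is even and diverse, autoclaved ("sterilized") soil carries only a
  handful of taxa at tiny yield, and treated soil is skewed toward a
  dominant taxon;
* reads are built as tag(s)+primer + insert + reverse-complemented
  primer+tag(s), strand-flipped with probability 1/2, then corrupted with
  i.i.d. per-base substitutions, insertions and deletions (defaults 3%
  each, nanopore-like); an optional chimera fraction swaps reverse-side
  tags between libraries.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import revcomp
from .io_formats import LineageRecord, Read, write_fastx, write_lineages
from .tag_design import LibraryPlan

#: Insert length ranges per marker, chosen so that a full tagged read
#: (insert + round-1 primers ~87 bp or round-2 primers ~139 bp) always lands
#: inside the marker's demux length window (16S 1200-1700, ITS 600-900).
INSERT_RANGES = {"16S": (1150, 1500), "ITS": (520, 750)}

KINGDOM_OF_MARKER = {"16S": "Bacteria", "ITS": "Fungi"}

RANK_PREFIXES = ("p", "c", "o", "f", "g", "s")

DEFAULT_ERROR_RATES = {"sub": 0.03, "ins": 0.03, "del": 0.03}

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class ReferenceSet:
    """Toy marker reference database with known lineages."""

    marker: str
    sequences: dict[str, str]
    lineages: dict[str, LineageRecord]
    insert_range: tuple[int, int]

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def write(self, fasta_path: str | Path, lineage_path: str | Path) -> None:
        write_fastx(
            fasta_path,
            (Read(rid, seq) for rid, seq in self.sequences.items()),
            "fasta",
        )
        write_lineages(lineage_path, self.lineages)


@dataclass
class CommunityProfile:
    """Taxon proportions for one sample (a point on the simplex)."""

    sample_id: str
    reference_ids: tuple[str, ...]
    proportions: np.ndarray
    relative_yield: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if len(p) != len(self.reference_ids):
            raise SimulationError("proportions/reference length mismatch")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise SimulationError("proportions must be a simplex vector")
        self.proportions = p

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.reference_ids, self.proportions))


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position independently with probability ``rate``."""
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hit):
        shift = rng.integers(1, 4, size=len(hit))
        codes = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(codes + shift) % 4]
    return out


def simulate_references(
    n_taxa: int,
    marker: str,
    tree_depth: int = 6,
    seed: int = 0,
    branch_substitution_rate: float = 0.03,
) -> ReferenceSet:
    """Evolve ``n_taxa`` reference sequences along a random taxonomy tree.

    The tree has ``tree_depth`` ranks below the kingdom; each internal node
    splits into 1-3 children, and every leaf is one reference taxon.  Sister
    taxa therefore share more sequence identity than distant taxa.  Leaf
    insert lengths are drawn uniformly from the marker's insert range.
    """
    if n_taxa < 1:
        raise SimulationError("n_taxa must be >= 1")
    if marker not in INSERT_RANGES:
        raise SimulationError(f"unknown marker {marker!r}")
    rng = np.random.default_rng(seed)
    lo, hi = INSERT_RANGES[marker]
    kingdom = KINGDOM_OF_MARKER[marker]
    root_seq = rng.choice(_BASES, size=hi)

    # recursively partition the leaf set, naming one taxon per rank level
    counters = {i: 0 for i in range(tree_depth)}
    leaves: list[tuple[tuple[str, ...], np.ndarray]] = []

    def grow(indices: list[int], depth: int, lineage: tuple[str, ...],
             seq: np.ndarray) -> None:
        if depth == tree_depth:
            for _ in indices:
                leaves.append((lineage, seq))
            return
        n_children = (
            len(indices) if depth == tree_depth - 1
            else min(len(indices), int(rng.integers(1, 4)))
        )
        splits = np.array_split(rng.permutation(indices), n_children)
        prefix = RANK_PREFIXES[min(depth, len(RANK_PREFIXES) - 1)]
        for part in splits:
            if len(part) == 0:
                continue
            counters[depth] += 1
            child_name = f"{prefix}{counters[depth]:03d}"
            child_seq = _mutate(seq, branch_substitution_rate, rng)
            grow(list(part), depth + 1, lineage + (child_name,), child_seq)

    grow(list(range(n_taxa)), 0, (kingdom,), root_seq)

    sequences: dict[str, str] = {}
    lineages: dict[str, LineageRecord] = {}
    for i, (lineage, seq) in enumerate(leaves):
        rid = f"{marker}_ref{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        sequences[rid] = "".join(seq[:length])
        lineages[rid] = LineageRecord(rid, lineage)
    return ReferenceSet(marker, sequences, lineages, (lo, hi))


def simulate_community(
    reference_set: ReferenceSet,
    profile_kind: str = "raw",
    seed: int = 0,
    sample_id: str = "sample",
) -> CommunityProfile:
    """Draw a community profile of the given kind.

    raw: even, diverse (symmetric Dirichlet alpha=5 over all taxa);
    sterilized: 1-3 surviving taxa at ~5% relative yield;
    post_treatment: skewed, one taxon holding at least half the community.
    """
    rng = np.random.default_rng(seed)
    ids = tuple(reference_set.ids)
    k = len(ids)
    if profile_kind == "raw":
        p = rng.dirichlet(np.full(k, 5.0))
        yield_ = 1.0
    elif profile_kind == "sterilized":
        n_surv = int(rng.integers(1, min(3, k) + 1))
        chosen = rng.choice(k, size=n_surv, replace=False)
        p = np.zeros(k)
        p[chosen] = rng.dirichlet(np.ones(n_surv))
        yield_ = 0.05
    elif profile_kind == "post_treatment":
        p = rng.dirichlet(np.full(k, 0.3))
        dom = int(rng.integers(k))
        p = 0.5 * p
        p[dom] += 0.5
        yield_ = 1.0
    else:
        raise SimulationError(f"unknown profile kind {profile_kind!r}")
    p = p / p.sum()
    return CommunityProfile(sample_id, ids, p, yield_)


# ---------------------------------------------------------------------------
# Read generation


def _apply_errors(
    seq: str, rates: Mapping[str, float], rng: np.random.Generator
) -> tuple[str, int]:
    """i.i.d. per-base substitution/insertion/deletion noise."""
    sub, ins, dele = rates["sub"], rates["ins"], rates["del"]
    if sub + ins + dele == 0:
        return seq, 0
    arr = np.array(list(seq))
    n = len(arr)
    sub_idx = np.nonzero(rng.random(n) < sub)[0]
    if len(sub_idx):
        shift = rng.integers(1, 4, size=len(sub_idx))
        codes = np.searchsorted(_BASES, arr[sub_idx])
        # N bases (absent from references) would break the shift trick;
        # references and primers are strict ACGT by construction
        arr[sub_idx] = _BASES[(codes + shift) % 4]
    del_mask = rng.random(n) < dele
    arr = arr[~del_mask]
    n_del = int(del_mask.sum())
    ins_mask = rng.random(len(arr) + 1) < ins
    ins_pos = np.nonzero(ins_mask)[0]
    if len(ins_pos):
        arr = np.insert(arr, ins_pos, rng.choice(_BASES, size=len(ins_pos)))
    n_err = len(sub_idx) + n_del + len(ins_pos)
    return "".join(arr), n_err


def simulate_reads(
    reference_sets: Mapping[str, ReferenceSet],
    profiles: Mapping[str, CommunityProfile],
    plans: Sequence[LibraryPlan],
    n_reads_per_library: int,
    error_rates: Mapping[str, float] | None = None,
    chimera_rate: float = 0.0,
    seed: int = 0,
    scale_by_yield: bool = False,
) -> tuple[list[Read], pd.DataFrame]:
    """Emit tagged, noisy reads for every library plan, with ground truth.

    ``profiles`` maps sample_id -> :class:`CommunityProfile` drawn over the
    marker's reference set.  Chimeric reads carry the forward primer of
    their own library and the reverse primer of another library of the same
    marker and round.  The truth table has one row per read (read_id,
    library_id, sample_id, marker, round, reference_id, strand, n_errors,
    is_chimera, partner_library).
    """
    rates = dict(DEFAULT_ERROR_RATES if error_rates is None else error_rates)
    for key in ("sub", "ins", "del"):
        if not 0 <= rates.get(key, 0) < 1:
            raise SimulationError(f"error rate {key} out of [0, 1)")
    if sum(rates.values()) >= 1:
        raise SimulationError("error rates sum to >= 1")
    if not 0 <= chimera_rate < 1:
        raise SimulationError("chimera_rate out of [0, 1)")

    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    truth_rows: list[dict] = []
    idx = 0
    for plan in plans:
        refs = reference_sets[plan.marker]
        profile = profiles[plan.sample_id]
        if profile.reference_ids != tuple(refs.ids):
            raise SimulationError(
                f"profile for {plan.sample_id} not over the {plan.marker} "
                "reference set"
            )
        n = n_reads_per_library
        if scale_by_yield:
            n = int(round(n * profile.relative_yield))
        if n == 0:
            continue
        ref_choice = rng.choice(len(profile.reference_ids), size=n,
                                p=profile.proportions)
        peers = [
            p for p in plans
            if p.marker == plan.marker and p.round == plan.round
            and p.library_id != plan.library_id
        ]
        for ref_i in ref_choice:
            idx += 1
            rid = f"read{idx:07d}"
            ref_id = profile.reference_ids[ref_i]
            insert = refs.sequences[ref_id]
            is_chimera = bool(peers) and rng.random() < chimera_rate
            partner = None
            rev_primer = plan.reverse_primer
            if is_chimera:
                partner = peers[int(rng.integers(len(peers)))]
                rev_primer = partner.reverse_primer
            # degenerate positions in the core resolve to a concrete base
            fwd_seq = _resolve_iupac(plan.forward_primer.full_sequence, rng)
            rev_seq = _resolve_iupac(rev_primer.full_sequence, rng)
            amplicon = fwd_seq + insert + revcomp(rev_seq)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                amplicon = revcomp(amplicon)
            noisy, n_err = _apply_errors(amplicon, rates, rng)
            reads.append(Read(rid, noisy, (20,) * len(noisy)))
            truth_rows.append(
                {
                    "read_id": rid,
                    "library_id": plan.library_id,
                    "sample_id": plan.sample_id,
                    "marker": plan.marker,
                    "round": plan.round,
                    "reference_id": ref_id,
                    "strand": strand,
                    "n_errors": n_err,
                    "is_chimera": is_chimera,
                    "partner_library": partner.library_id if partner else ".",
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "library_id", "sample_id", "marker", "round",
            "reference_id", "strand", "n_errors", "is_chimera",
            "partner_library",
        ],
    )
    return reads, truth


_IUPAC_CHOICES = {
    "M": "AC", "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _resolve_iupac(seq: str, rng: np.random.Generator) -> str:
    if not set(seq) - set("ACGT"):
        return seq
    return "".join(
        b if b in "ACGT" else _IUPAC_CHOICES[b][int(rng.integers(len(_IUPAC_CHOICES[b])))]
        for b in seq
    )


def write_truth(path: str | Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
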