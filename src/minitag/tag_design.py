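"""Nested dual-tag primer scheme and experimental-design expansion.

The study design this reproduces: amplicons of the bacterial 16S rRNA gene
(27F/1492R) and the fungal ITS region (ITS1F/ITS4) from multiple soil and
leaf DNA samples, pooled into one nanopore run.  Sample identity is encoded
by a 24 bp tag prepended to both PCR primers in a first ("round 1") PCR;
a second nested PCR ("round 2") prepends an additional 26 bp tag to the 5'
end of each round-1 tagged primer, so every round-2 primer contains its
round-1 primer as an exact suffix.

Tag sequences themselves are generated here (random, pairwise edit distance
constrained) rather than transcribed from any published appendix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .align import revcomp

TAG1_LENGTH = 24
TAG2_LENGTH = 26

#: The four fixed marker primers (IUPAC codes preserved).
PRIMER_CORES: dict[tuple[str, str], str] = {
    ("16S", "forward"): "AGAGTTTGATCMTGGCTCAG",   # 27F
    ("16S", "reverse"): "GGTTACCTTGTTACGACTT",    # 1492R
    ("ITS", "forward"): "TCCGTAGGTGAACCTGCGG",    # ITS1F
    ("ITS", "reverse"): "TCCTCCGCTTATTGATATGC",   # ITS4
}

CORE_NAMES = {
    ("16S", "forward"): "27F",
    ("16S", "reverse"): "1492R",
    ("ITS", "forward"): "ITS1F",
    ("ITS", "reverse"): "ITS4",
}


def fixed_primers() -> dict[tuple[str, str], str]:
    """Return the four marker core primers keyed by (marker, orientation)."""
    return dict(PRIMER_CORES)


class TagDesignError(ValueError):
    pass


@dataclass(frozen=True)
class TaggedPrimer:
    """A tagged PCR primer: [tag2 +] tag1 + core.

    tag2 is empty for round-1 primers and 26 bp for round-2 primers; tag1 is
    always 24 bp.  ``full_sequence`` is the synthesised oligo 5'->3'.
    """

    name: str
    marker: str
    orientation: str
    round: int
    tag1: str
    tag2: str = ""
    core: str = field(default="")

    def __post_init__(self) -> None:
        if self.marker not in ("16S", "ITS"):
            raise TagDesignError(f"unknown marker {self.marker!r}")
        if self.orientation not in ("forward", "reverse"):
            raise TagDesignError(f"unknown orientation {self.orientation!r}")
        core = self.core or PRIMER_CORES[(self.marker, self.orientation)]
        object.__setattr__(self, "core", core)
        if core != PRIMER_CORES[(self.marker, self.orientation)]:
            raise TagDesignError(
                f"{self.name}: core is not the fixed {self.marker} "
                f"{self.orientation} primer"
            )
        if len(self.tag1) != TAG1_LENGTH:
            raise TagDesignError(f"{self.name}: tag1 must be {TAG1_LENGTH} bp")
        if self.round == 1:
            if self.tag2:
                raise TagDesignError(f"{self.name}: round-1 primer with tag2")
        elif self.round == 2:
            if len(self.tag2) != TAG2_LENGTH:
                raise TagDesignError(
                    f"{self.name}: tag2 must be {TAG2_LENGTH} bp"
                )
        else:
            raise TagDesignError(f"{self.name}: round must be 1 or 2")
        for tag in (self.tag1, self.tag2):
            if set(tag) - set("ACGT"):
                raise TagDesignError(f"{self.name}: tag has non-ACGT bases")

    @property
    def full_sequence(self) -> str:
        return self.tag2 + self.tag1 + self.core

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass(frozen=True)
class LibraryPlan:
    """One tagged amplicon library: a sample amplified with one primer pair."""

    library_id: str
    sample_id: str
    marker: str
    round: int
    forward_primer: TaggedPrimer
    reverse_primer: TaggedPrimer
    input_mass_ng: float = 0.49

    def __post_init__(self) -> None:
        fp, rp = self.forward_primer, self.reverse_primer
        if fp.marker != self.marker or rp.marker != self.marker:
            raise TagDesignError(f"{self.library_id}: primer/marker mismatch")
        if fp.round != self.round or rp.round != self.round:
            raise TagDesignError(f"{self.library_id}: primer/round mismatch")
        if fp.orientation != "forward" or rp.orientation != "reverse":
            raise TagDesignError(f"{self.library_id}: primer orientations wrong")


# ---------------------------------------------------------------------------
# Tag generation


def _has_long_homopolymer(tag: str, max_run: int = 3) -> bool:
    run = 1
    for a, b in zip(tag, tag[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return True
    return False


def _gc_fraction(tag: str) -> float:
    return (tag.count("G") + tag.count("C")) / len(tag)


def _shares_core_kmer(tag: str, cores: Sequence[str], k: int = 12) -> bool:
    """True if tag contains a >=k-base exact match to any core or its rc."""
    targets = [c for core in cores for c in (core, revcomp(core))]
    for i in range(len(tag) - k + 1):
        kmer = tag[i : i + k]
        if any(kmer in t for t in targets):
            return True
    return False


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def generate_tags(
    n: int,
    length: int,
    min_pairwise_edit_distance: int = 8,
    seed: int = 0,
    max_attempts_per_tag: int = 2000,
) -> list[str]:
    """Generate ``n`` distinct sample tags of the given length.

    Constraints: pairwise edit distance >= ``min_pairwise_edit_distance``
    between every accepted pair, GC content in [0.4, 0.6], homopolymer runs
    capped at 3, and no 12-base exact match to any core primer or its
    reverse complement.  Deterministic for a given seed; raises
    :class:`TagDesignError` when the constraints prove infeasible within the
    bounded retry budget.
    """
    if n < 1:
        raise TagDesignError("n must be >= 1")
    if 4**length < n:
        raise TagDesignError(
            f"cannot draw {n} distinct tags of length {length}"
        )
    rng = np.random.default_rng(seed)
    cores = list(PRIMER_CORES.values())
    bases = np.array(list("ACGT"))
    tags: list[str] = []
    attempts = 0
    budget = max_attempts_per_tag * n
    while len(tags) < n:
        attempts += 1
        if attempts > budget:
            raise TagDesignError(
                f"could not generate {n} tags of length {length} with "
                f"min edit distance {min_pairwise_edit_distance} in "
                f"{budget} attempts"
            )
        cand = "".join(rng.choice(bases, size=length))
        if not 0.4 <= _gc_fraction(cand) <= 0.6:
            continue
        if _has_long_homopolymer(cand):
            continue
        if length >= 12 and _shares_core_kmer(cand, cores):
            continue
        if any(
            edit_distance(cand, t) < min_pairwise_edit_distance for t in tags
        ):
            continue
        tags.append(cand)
    return tags


# ---------------------------------------------------------------------------
# Design expansion


@dataclass(frozen=True)
class DesignConfig:
    """Description of the sampling/PCR design to expand into libraries.

    Defaults reproduce the study layout: twelve 300 g soil containers, six
    raw (I-VI) and six autoclave-sterilised (1-6); containers I-III and 1-3
    sampled once and IV-VI and 4-6 sampled twice at each of two time points
    (A = start, B = after two weeks), plus two fallen-leaf samples.  All 38
    DNA extracts template the 16S round-1 PCR; the single-sampled containers
    and the leaves (14 samples) template 16S round 2 and both ITS rounds.
    """

    single_containers: tuple[str, ...] = ("I", "II", "III", "1", "2", "3")
    double_containers: tuple[str, ...] = ("IV", "V", "VI", "4", "5", "6")
    times: tuple[str, ...] = ("A", "B")
    n_leaf_samples: int = 2
    markers: tuple[str, ...] = ("16S", "ITS")
    input_mass_ng: float = 0.49
    tag_seed: int = 20211109
    min_tag1_distance: int = 8
    min_tag2_distance: int = 9

    def all_sample_ids(self) -> list[str]:
        """Every DNA extract, in deterministic order."""
        samples: list[str] = []
        for time in self.times:
            for c in self.single_containers:
                samples.append(f"{time}-{c}")
            for c in self.double_containers:
                samples.append(f"{time}-{c}-1")
                samples.append(f"{time}-{c}-2")
        samples.extend(f"Leaf-{i + 1}" for i in range(self.n_leaf_samples))
        return samples

    def subset_sample_ids(self) -> list[str]:
        """Samples carried into round 2 and the ITS marker."""
        samples = [
            f"{time}-{c}"
            for time in self.times
            for c in self.single_containers
        ]
        samples.extend(f"Leaf-{i + 1}" for i in range(self.n_leaf_samples))
        return samples


def expand_design(config: DesignConfig | None = None) -> list[LibraryPlan]:
    """Expand a design into one :class:`LibraryPlan` per tagged amplicon.

    Under the default config this yields 80 libraries: 38 (16S round 1) +
    14 (16S round 2) + 14 (ITS round 1) + 14 (ITS round 2); 52 round-1 and
    28 round-2 in total.  Pure function of its config: identical config
    gives identical output order.
    """
    config = config or DesignConfig()
    all_samples = config.all_sample_ids()
    if len(set(all_samples)) != len(all_samples):
        raise TagDesignError("duplicate sample ids in design")
    subset = config.subset_sample_ids()

    tag1s = generate_tags(
        len(all_samples), TAG1_LENGTH, config.min_tag1_distance,
        seed=config.tag_seed,
    )
    tag2s = generate_tags(
        len(subset), TAG2_LENGTH, config.min_tag2_distance,
        seed=config.tag_seed + 1,
    )
    tag1_of = dict(zip(all_samples, tag1s))
    tag2_of = dict(zip(subset, tag2s))

    def primer_pair(sample: str, marker: str, rnd: int):
        tag1 = tag1_of[sample]
        tag2 = tag2_of[sample] if rnd == 2 else ""
        prefix = f"{marker}-r{rnd}-{sample}"
        fwd = TaggedPrimer(
            name=f"{prefix}-F", marker=marker, orientation="forward",
            round=rnd, tag1=tag1, tag2=tag2,
        )
        rev = TaggedPrimer(
            name=f"{prefix}-R", marker=marker, orientation="reverse",
            round=rnd, tag1=tag1, tag2=tag2,
        )
        return fwd, rev

    plans: list[LibraryPlan] = []

    def add(samples: Iterable[str], marker: str, rnd: int) -> None:
        for sample in samples:
            fwd, rev = primer_pair(sample, marker, rnd)
            plans.append(
                LibraryPlan(
                    library_id=f"{marker}-r{rnd}-{sample}",
                    sample_id=sample,
                    marker=marker,
                    round=rnd,
                    forward_primer=fwd,
                    reverse_primer=rev,
                    input_mass_ng=config.input_mass_ng,
                )
            )

    if "16S" in config.markers:
        add(all_samples, "16S", 1)
        add(subset, "16S", 2)
    if "ITS" in config.markers:
        add(subset, "ITS", 1)
        add(subset, "ITS", 2)

    seen: set[str] = set()
    for p in plans:
        if p.library_id in seen:
            raise TagDesignError(f"duplicate library id {p.library_id}")
        seen.add(p.library_id)
    return plans


# ---------------------------------------------------------------------------
# Primer sheet I/O

_SHEET_HEADER = [
    "library_id", "sample_id", "marker", "round",
    "fwd_name", "fwd_sequence", "rev_name", "rev_sequence", "input_mass_ng",
]


def write_primer_sheet(path: str | Path, plans: Sequence[LibraryPlan]) -> int:
    with open(path, "w") as fh:
        fh.write("\t".join(_SHEET_HEADER) + "\n")
        for p in plans:
            fh.write(
                "\t".join(
                    [
                        p.library_id, p.sample_id, p.marker, str(p.round),
                        p.forward_primer.name, p.forward_primer.full_sequence,
                        p.reverse_primer.name, p.reverse_primer.full_sequence,
                        repr(p.input_mass_ng),
                    ]
                )
                + "\n"
            )
    return len(plans)


def _primer_from_sheet(name: str, seq: str, marker: str, rnd: int,
                       orientation: str) -> TaggedPrimer:
    core = PRIMER_CORES[(marker, orientation)]
    if not seq.endswith(core):
        raise TagDesignError(f"{name}: sequence does not end with {marker} core")
    tags = seq[: -len(core)]
    if rnd == 1:
        tag2, tag1 = "", tags
    else:
        tag2, tag1 = tags[:TAG2_LENGTH], tags[TAG2_LENGTH:]
    return TaggedPrimer(
        name=name, marker=marker, orientation=orientation, round=rnd,
        tag1=tag1, tag2=tag2,
    )


def read_primer_sheet(path: str | Path) -> list[LibraryPlan]:
    plans: list[LibraryPlan] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SHEET_HEADER:
            raise TagDesignError(f"{path}: unexpected primer sheet header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_SHEET_HEADER):
                raise TagDesignError(f"{path}:{lineno}: wrong column count")
            (lib, sample, marker, rnd_s, fname, fseq, rname, rseq, mass) = parts
            rnd = int(rnd_s)
            plans.append(
                LibraryPlan(
                    library_id=lib, sample_id=sample, marker=marker, round=rnd,
                    forward_primer=_primer_from_sheet(fname, fseq, marker, rnd, "forward"),
                    reverse_primer=_primer_from_sheet(rname, rseq, marker, rnd, "reverse"),
                    input_mass_ng=float(mass),
                )
            )
    names = [p.forward_primer.name for p in plans] + [
        p.reverse_primer.name for p in plans
    ]
    dupes = {n for n, c in zip(names, map(names.count, names)) if c > 1}
    if dupes:
        raise TagDesignError(f"{path}: duplicate primer names {sorted(dupes)}")
    return plans
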