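"""IUPAC-aware local alignment of short primers against long reads.

Scoring follows blastn-like defaults for short, high-identity matches:
match +1, mismatch -2, affine gaps with open 2 and extend 1 (a gap of
length g costs 2 + g).  Degenerate IUPAC codes in the primer (e.g. the M
in 27F) match any of their bases at full match score; N in a read matches
nothing.

The pairwise entry point :func:`smith_waterman` is exact full dynamic
programming with traceback; :func:`local_align_all` peels off all
non-overlapping local alignments above a score floor, on both strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MATCH = 1.0
MISMATCH = -2.0
GAP_OPEN = 2.0
GAP_EXTEND = 1.0

# 4-bit encodings: one bit per concrete base, IUPAC codes as unions.
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7,
    "N": 0,  # N never matches
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA (with IUPAC codes) as a uint8 bitmask vector."""
    try:
        return np.array([_IUPAC_BITS[b] for b in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid DNA character {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a query against a target.

    Coordinates are 0-based half-open on the sequences as given.
    ``query_aligned`` counts query positions consumed (for primer coverage).
    """

    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    matches: int
    mismatches: int
    gap_opens: int
    gaps: int

    @property
    def query_aligned(self) -> int:
        return self.query_end - self.query_start

    @property
    def alignment_length(self) -> int:
        # aligned columns = matched/mismatched pairs + gap bases
        return self.matches + self.mismatches + self.gaps

    @property
    def percent_identity(self) -> float:
        n = self.alignment_length
        return 100.0 * self.matches / n if n else 0.0


def _dp_matrices(q: np.ndarray, t: np.ndarray):
    """Fill H/E/F matrices for affine-gap local alignment (rows = query)."""
    m, n = len(q), len(t)
    neg = -np.inf
    H = np.zeros((m + 1, n + 1), dtype=np.float64)
    E = np.full((m + 1, n + 1), neg)  # gap in target (vertical, consumes query)
    F = np.full((m + 1, n + 1), neg)  # gap in query (horizontal, consumes target)
    match_mask = (q[:, None] & t[None, :]) != 0
    S = np.where(match_mask, MATCH, MISMATCH)
    for i in range(1, m + 1):
        E[i] = np.maximum(E[i - 1], H[i - 1] - GAP_OPEN) - GAP_EXTEND
        diag = H[i - 1, :-1] + S[i - 1]
        h_nof = np.maximum(E[i, 1:], diag)
        h_nof = np.maximum(h_nof, 0.0)
        # exact horizontal pass: F[j] = max_{j'<j} (H[j'] - open - ext*(j-j'))
        # resolved with a prefix max because a gap-from-gap is covered by a
        # longer gap from the same origin under affine costs
        idx = np.arange(n + 1, dtype=np.float64)
        cum = np.maximum.accumulate(h_nof + GAP_EXTEND * idx[1:])
        F[i, 2:] = cum[:-1] - GAP_OPEN - GAP_EXTEND * idx[2:]
        F[i, 1] = neg
        H[i, 1:] = np.maximum(h_nof, F[i, 1:])
    return H, E, F, S


def _traceback(H, E, F, S, i: int, j: int) -> LocalAlignment:
    """Walk back from cell (i, j) of H to the start of the local alignment."""
    score = H[i, j]
    qe, te = i, j
    matches = mismatches = gap_opens = gaps = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            if i > 0 and j > 0 and math.isclose(H[i, j], H[i - 1, j - 1] + S[i - 1, j - 1]):
                if S[i - 1, j - 1] > 0:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif math.isclose(H[i, j], E[i, j]):
                state = "E"
            elif math.isclose(H[i, j], F[i, j]):
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed")
        elif state == "E":
            gaps += 1
            if math.isclose(E[i, j], H[i - 1, j] - GAP_OPEN - GAP_EXTEND):
                gap_opens += 1
                state = "H"
            i -= 1
        else:  # F
            gaps += 1
            if math.isclose(F[i, j], H[i, j - 1] - GAP_OPEN - GAP_EXTEND):
                gap_opens += 1
                state = "H"
            j -= 1
    return LocalAlignment(
        score=float(score),
        query_start=i,
        query_end=qe,
        target_start=j,
        target_end=te,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        gaps=gaps,
    )


def smith_waterman(query: str, target: str) -> LocalAlignment | None:
    """Best local alignment of ``query`` against ``target`` (exact full DP).

    Returns None when no cell scores above zero.  Ties are broken toward the
    smallest (query_end, target_end) cell so the result is deterministic.
    """
    q, t = encode(query), encode(target)
    H, E, F, S = _dp_matrices(q, t)
    best = H.max()
    if best <= 0:
        return None
    ii, jj = np.argwhere(H == best)[0]
    return _traceback(H, E, F, S, int(ii), int(jj))


def local_align_all(
    query: str, target: str, score_floor: float = 18.0
) -> list[LocalAlignment]:
    """All non-overlapping (on the target) local alignments scoring >= floor.

    Greedy: take the best alignment, split the target around it, recurse on
    the flanks.  Results are sorted by target_start.
    """
    out: list[LocalAlignment] = []

    def recurse(t_sub: str, offset: int) -> None:
        if len(t_sub) == 0:
            return
        aln = smith_waterman(query, t_sub)
        if aln is None or aln.score < score_floor:
            return
        shifted = LocalAlignment(
            score=aln.score,
            query_start=aln.query_start,
            query_end=aln.query_end,
            target_start=aln.target_start + offset,
            target_end=aln.target_end + offset,
            matches=aln.matches,
            mismatches=aln.mismatches,
            gap_opens=aln.gap_opens,
            gaps=aln.gaps,
        )
        out.append(shifted)
        recurse(t_sub[: aln.target_start], offset)
        recurse(t_sub[aln.target_end :], offset + aln.target_end)

    recurse(target, 0)
    out.sort(key=lambda a: a.target_start)
    return out


def bitscore(raw_score: float, lambda_: float = 0.625, K: float = 0.41) -> float:
    """Karlin–Altschul normalised score in bits: (lambda*raw - ln K) / ln 2.

    Defaults are the gapped blastn parameters for the +1/-2 scoring used by
    the primer aligner; monotone increasing in raw_score.
    """
    if lambda_ <= 0 or K <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    return (lambda_ * raw_score - math.log(K)) / math.log(2)
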