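"""Taxa-as-OTU tables and per-sample community statistics.

Every distinct LCA-assigned lineage is one OTU.  The per-marker table is
filtered in a fixed order — kingdom first (Fungi for ITS, Bacteria for
16S), then a minimum total count of 2 reads across all samples — and the
per-sample summary reproduces the standard report columns:

* N      — reads assigned to the sample by demultiplexing
* OTU    — retained taxa observed in the sample
* Ns     — reads of the sample contained in retained taxa
* Ns/ng  — Ns scaled to 1 ng of pooled amplicon input
* S      — Shannon diversity (natural log)
* R      — reciprocal Berger-Parker dominance (1 / share of the most
           abundant taxon)

Bray-Curtis dissimilarities between samples are exported for downstream
ordination/clustering tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy

from .taxonomy_lca import TaxAssignment

DEFAULT_MIN_READS = 2
DEFAULT_INPUT_MASS_NG = 0.49

ROOT_TAXON = "root"


class CommunityError(ValueError):
    pass


@dataclass
class OTUTable:
    """Samples x taxa count matrix; taxa are full lineage strings.

    ``counts`` is a pandas DataFrame with taxa as the index and sample
    (library) ids as columns; values are non-negative integers and no row
    is all-zero.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise CommunityError("negative counts")
        self.counts = self.counts.astype(int)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def drop_empty_taxa(self) -> "OTUTable":
        keep = self.counts.sum(axis=1) > 0
        return OTUTable(self.counts.loc[keep])

    def write_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OTUTable":
        df = pd.read_csv(path, sep="\t", index_col="taxon")
        return cls(df)


def build_otu_table(
    assignments: Sequence[TaxAssignment],
    library_of_read: Mapping[str, str],
    samples: Sequence[str] | None = None,
) -> OTUTable:
    """Cross-tabulate assignments into a taxa x samples count table.

    ``library_of_read`` maps read ids to their demultiplexed library;
    ``samples`` fixes the column set and order (defaults to the libraries
    observed, sorted).
    """
    rows: dict[tuple[str, str], int] = {}
    seen_samples: set[str] = set()
    for a in assignments:
        lib = library_of_read.get(a.read_id)
        if lib is None:
            raise CommunityError(
                f"assignment for unknown read {a.read_id!r} (no library)"
            )
        seen_samples.add(lib)
        key = (a.taxon, lib)
        rows[key] = rows.get(key, 0) + 1
    cols = list(samples) if samples is not None else sorted(seen_samples)
    taxa = sorted({t for t, _ in rows})
    mat = pd.DataFrame(0, index=taxa, columns=cols, dtype=int)
    for (taxon, lib), c in rows.items():
        if lib in mat.columns:
            mat.loc[taxon, lib] = c
    return OTUTable(mat).drop_empty_taxa()


def kingdom_filter(table: OTUTable, kingdom: str) -> OTUTable:
    """Keep taxa whose root-most rank equals ``kingdom``.

    Root-assigned taxa (the ``root`` placeholder) never match and are
    removed here.
    """
    keep = [
        t
        for t in table.taxa
        if t != ROOT_TAXON and t.split(";")[0] == kingdom
    ]
    return OTUTable(table.counts.loc[keep])


def min_count_filter(
    table: OTUTable,
    min_reads: int = DEFAULT_MIN_READS,
    per_sample: bool = False,
) -> OTUTable:
    """Drop rare taxa.

    By default a taxon is kept when its total count across all samples is at
    least ``min_reads`` (the pooled reading of the two-or-more-reads rule);
    ``per_sample=True`` instead zeroes, per sample, cells below
    ``min_reads`` before dropping empty taxa.
    """
    if per_sample:
        counts = table.counts.where(table.counts >= min_reads, 0)
        return OTUTable(counts).drop_empty_taxa()
    keep = table.counts.sum(axis=1) >= min_reads
    return OTUTable(table.counts.loc[keep])


# ---------------------------------------------------------------------------
# Per-sample statistics


def shannon(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity S = -sum p_i ln p_i; NaN for an all-zero profile."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        return float("nan")
    return float(entropy(c[c > 0]))


def dominance_reciprocal(counts: Sequence[float] | np.ndarray) -> float:
    """Reciprocal Berger-Parker dominance R = 1 / max_i p_i; NaN when empty."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        return float("nan")
    return float(total / c.max())


def reads_per_ng(ns: float, input_mass_ng: float) -> float:
    """Reads per nanogram of pooled amplicon DNA."""
    if input_mass_ng <= 0:
        raise CommunityError("input mass must be positive")
    return ns / input_mass_ng


def sample_stats(
    filtered_table: OTUTable,
    demux_n: Mapping[str, int],
    input_mass_ng: Mapping[str, float] | float = DEFAULT_INPUT_MASS_NG,
) -> pd.DataFrame:
    """Per-sample summary with columns N, OTU, Ns, Ns/ng, S, R.

    ``filtered_table`` should already have the kingdom and minimum-count
    filters applied; ``demux_n`` is the assigned-read count per sample from
    demultiplexing.  S and R are computed on the filtered per-sample
    profile and reported as NaN for samples with no retained reads.
    """
    rows = []
    for s in filtered_table.samples:
        col = filtered_table.counts[s].to_numpy()
        ns = int(col.sum())
        n = int(demux_n.get(s, 0))
        if ns > n:
            raise CommunityError(
                f"sample {s}: Ns={ns} exceeds demultiplexed N={n}"
            )
        mass = (
            input_mass_ng.get(s, DEFAULT_INPUT_MASS_NG)
            if isinstance(input_mass_ng, Mapping)
            else float(input_mass_ng)
        )
        rows.append(
            {
                "sample": s,
                "N": n,
                "OTU": int((col > 0).sum()),
                "Ns": ns,
                "Ns/ng": reads_per_ng(ns, mass),
                "S": shannon(col),
                "R": dominance_reciprocal(col),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def bray_curtis_matrix(table: OTUTable) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity between all sample pairs.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), in [0, 1].  Pairs involving a
    sample with zero total are reported as NaN.
    """
    if len(table.samples) < 2:
        raise CommunityError("need at least two samples")
    X = table.counts.to_numpy(dtype=float).T  # samples x taxa
    totals = X.sum(axis=1)
    with np.errstate(invalid="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    D[totals == 0, :] = np.nan
    D[:, totals == 0] = np.nan
    np.fill_diagonal(D, [0.0 if t > 0 else np.nan for t in totals])
    return pd.DataFrame(D, index=table.samples, columns=table.samples)


def phylum_rollup(table: OTUTable, rank: int = 2) -> pd.DataFrame:
    """Aggregate counts at lineage rank ``rank`` (1-based from the root).

    With the default rank 2 this is the phylum level for kingdom-rooted
    lineages; taxa shallower than ``rank`` aggregate under their full
    lineage.
    """
    labels = [
        ";".join(t.split(";")[:rank]) if t != ROOT_TAXON else ROOT_TAXON
        for t in table.taxa
    ]
    return table.counts.groupby(labels).sum()
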