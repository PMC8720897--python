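import math

import numpy as np
import pandas as pd
import pytest

from minitag.community import (
    CommunityError,
    OTUTable,
    bray_curtis_matrix,
    build_otu_table,
    dominance_reciprocal,
    kingdom_filter,
    min_count_filter,
    phylum_rollup,
    reads_per_ng,
    sample_stats,
    shannon,
)
from minitag.taxonomy_lca import TaxAssignment


def ta(read_id, lineage, bits=150.0):
    return TaxAssignment(read_id, lineage, bits, 1)


def table_from(dict_of_cols):
    return OTUTable(pd.DataFrame(dict_of_cols).fillna(0).astype(int))


class TestBuildTable:
    def test_counts_per_library(self):
        assigns = [
            ta("r1", ("Bacteria", "X")), ta("r2", ("Bacteria", "X")),
            ta("r3", ("Bacteria", "X")), ta("r4", ("Bacteria", "Y")),
        ]
        libs = {f"r{i}": "L1" for i in range(1, 5)}
        t = build_otu_table(assigns, libs)
        assert t.counts.loc["Bacteria;X", "L1"] == 3
        assert t.counts.loc["Bacteria;Y", "L1"] == 1

    def test_disjoint_taxa_block_structure(self):
        assigns = [ta("r1", ("Bacteria", "X")), ta("r2", ("Bacteria", "Y"))]
        libs = {"r1": "L1", "r2": "L2"}
        t = build_otu_table(assigns, libs)
        assert t.counts.loc["Bacteria;X", "L2"] == 0
        assert t.counts.loc["Bacteria;Y", "L1"] == 0

    def test_no_all_zero_rows(self):
        assigns = [ta("r1", ("Bacteria", "X"))]
        t = build_otu_table(assigns, {"r1": "L1"}, samples=["L1", "L2"])
        assert (t.counts.sum(axis=1) > 0).all()


class TestFilters:
    def test_kingdom_filter_drops_root_and_other_kingdoms(self):
        t = table_from({"L1": pd.Series({
            "Fungi;Asco": 5, "Bacteria;Proteo": 3, "root": 2,
        })})
        kept = kingdom_filter(t, "Fungi")
        assert kept.taxa == ["Fungi;Asco"]
        all_fungi = table_from({"L1": pd.Series({"Fungi;A": 1, "Fungi;B": 2})})
        assert kingdom_filter(all_fungi, "Fungi").taxa == all_fungi.taxa

    def test_kingdom_filter_matches_linear_scan(self, rng):
        taxa = {
            f"{k};p{i}": rng.integers(1, 10, size=3)
            for i in range(10)
            for k in ("Fungi", "Bacteria")
        }
        df = pd.DataFrame(taxa, index=["L1", "L2", "L3"]).T
        t = OTUTable(df)
        kept = kingdom_filter(t, "Bacteria")
        expected = [x for x in df.index if x.split(";")[0] == "Bacteria"]
        assert kept.taxa == expected

    def test_min_count_total_across_samples(self):
        t = table_from({
            "L1": pd.Series({"Fungi;A": 1, "Fungi;B": 1, "Fungi;C": 5}),
            "L2": pd.Series({"Fungi;A": 1, "Fungi;B": 0, "Fungi;C": 0}),
        })
        kept = min_count_filter(t, 2)
        # A: 1+1=2 kept; B: 1 dropped; C: 5 kept
        assert sorted(kept.taxa) == ["Fungi;A", "Fungi;C"]

    def test_min_count_per_sample_variant(self):
        t = table_from({
            "L1": pd.Series({"Fungi;A": 1, "Fungi;C": 5}),
            "L2": pd.Series({"Fungi;A": 1, "Fungi;C": 0}),
        })
        kept = min_count_filter(t, 2, per_sample=True)
        assert kept.taxa == ["Fungi;C"]

    def test_empty_table_stays_empty(self):
        t = OTUTable(pd.DataFrame({"L1": []}, dtype=int))
        assert min_count_filter(t).taxa == []

    def test_filter_order_kingdom_then_mincount(self):
        # a Fungi taxon at total 2 must survive even though a same-name-level
        # Bacteria taxon is removed first; order swap would not change this
        # case, but min-count on the pre-kingdom table would keep Bacteria;B
        t = table_from({
            "L1": pd.Series({"Fungi;A": 2, "Bacteria;B": 7}),
        })
        out = min_count_filter(kingdom_filter(t, "Fungi"), 2)
        assert out.taxa == ["Fungi;A"]


class TestDiversityStats:
    def test_shannon_single_taxon_is_zero(self):
        assert shannon([17]) == 0.0

    def test_shannon_uniform_is_ln_k(self):
        for k in (2, 5, 11):
            assert shannon([7] * k) == pytest.approx(math.log(k))

    def test_shannon_direct_summation(self):
        counts = [5, 3, 2]
        p = np.array(counts) / 10
        expected = -sum(pi * math.log(pi) for pi in p)
        assert shannon(counts) == pytest.approx(expected)

    def test_shannon_empty_is_nan(self):
        assert math.isnan(shannon([0, 0]))

    def test_dominance_reciprocal(self):
        assert dominance_reciprocal([42]) == 1.0
        assert dominance_reciprocal([3] * 7) == pytest.approx(7.0)
        assert dominance_reciprocal([5, 3, 2]) == pytest.approx(2.0)
        assert math.isnan(dominance_reciprocal([0]))

    def test_reads_per_ng(self):
        assert reads_per_ng(49, 0.49) == pytest.approx(100.0)
        assert reads_per_ng(0, 0.49) == 0.0
        assert reads_per_ng(123, 1.0) == 123.0
        with pytest.raises(CommunityError):
            reads_per_ng(10, 0)


class TestSampleStats:
    def test_columns_and_invariants(self):
        t = table_from({
            "L1": pd.Series({"Fungi;A": 5, "Fungi;B": 3, "Fungi;C": 2}),
            "L2": pd.Series({"Fungi;A": 4, "Fungi;B": 0, "Fungi;C": 0}),
        })
        stats = sample_stats(t, {"L1": 12, "L2": 6}, 0.49)
        assert list(stats.columns) == ["N", "OTU", "Ns", "Ns/ng", "S", "R"]
        assert stats.loc["L1", "N"] == 12
        assert stats.loc["L1", "OTU"] == 3
        assert stats.loc["L1", "Ns"] == 10
        assert stats.loc["L1", "Ns/ng"] == pytest.approx(10 / 0.49)
        assert stats.loc["L1", "R"] == pytest.approx(2.0)
        assert (stats["Ns"] <= stats["N"]).all()
        assert stats.loc["L2", "S"] == 0.0
        assert stats.loc["L2", "R"] == 1.0

    def test_ns_exceeding_n_is_an_error(self):
        t = table_from({"L1": pd.Series({"Fungi;A": 5})})
        with pytest.raises(CommunityError):
            sample_stats(t, {"L1": 3})


class TestBrayCurtis:
    def test_identical_and_disjoint_columns(self):
        t = table_from({
            "A": pd.Series({"t1": 3, "t2": 2, "t3": 0, "t4": 0}),
            "B": pd.Series({"t1": 3, "t2": 2, "t3": 0, "t4": 0}),
            "C": pd.Series({"t1": 0, "t2": 0, "t3": 4, "t4": 1}),
        })
        d = bray_curtis_matrix(t)
        assert d.loc["A", "B"] == pytest.approx(0.0)
        assert d.loc["A", "C"] == pytest.approx(1.0)
        assert np.allclose(d.values, d.values.T)

    def test_matches_double_loop_oracle(self, rng):
        counts = rng.integers(0, 20, size=(5, 4))
        t = OTUTable(pd.DataFrame(
            counts, index=[f"t{i}" for i in range(5)],
            columns=list("ABCD"),
        ))
        d = bray_curtis_matrix(t)
        for a in range(4):
            for b in range(4):
                x, y = counts[:, a], counts[:, b]
                expected = np.abs(x - y).sum() / (x + y).sum()
                assert d.iloc[a, b] == pytest.approx(expected)

    def test_zero_total_sample_reported_missing(self):
        t = table_from({
            "A": pd.Series({"t1": 3}), "B": pd.Series({"t1": 0}),
        })
        d = bray_curtis_matrix(t)
        assert math.isnan(d.loc["A", "B"])
        assert math.isnan(d.loc["B", "B"])
        assert d.loc["A", "A"] == 0.0


class TestPhylumRollup:
    def test_rollup_conserves_column_sums(self, rng):
        taxa = [f"Fungi;p{i % 3};c{i}" for i in range(9)]
        df = pd.DataFrame(
            rng.integers(0, 9, size=(9, 2)), index=taxa, columns=["L1", "L2"]
        )
        t = OTUTable(df)
        rolled = phylum_rollup(t)
        assert (rolled.sum() == df.sum()).all()
        assert sorted(rolled.index) == ["Fungi;p0", "Fungi;p1", "Fungi;p2"]

    def test_rollup_matches_groupby_oracle(self, rng):
        taxa = [f"Fungi;p{i % 2};c{i};o{i}" for i in range(6)]
        df = pd.DataFrame(
            rng.integers(0, 5, size=(6, 3)), index=taxa,
            columns=["L1", "L2", "L3"],
        )
        rolled = phylum_rollup(OTUTable(df))
        manual = {}
        for taxon, row in df.iterrows():
            key = ";".join(taxon.split(";")[:2])
            for lib, v in row.items():
                manual[(key, lib)] = manual.get((key, lib), 0) + v
        for (key, lib), v in manual.items():
            assert rolled.loc[key, lib] == v
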