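import numpy as np
import pytest

import edlib

from minitag.community import shannon
from minitag.simulator import (
    INSERT_RANGES,
    SimulationError,
    simulate_community,
    simulate_reads,
    simulate_references,
)
from minitag.tag_design import expand_design, DesignConfig


class TestSimulateReferences:
    def test_single_taxon_lineage_depth(self):
        refs = simulate_references(1, "16S", tree_depth=6, seed=0)
        assert len(refs.sequences) == 1
        (lineage,) = refs.lineages.values()
        # kingdom + tree_depth ranks
        assert len(lineage.ranks) == 7
        assert lineage.ranks[0] == "Bacteria"

    def test_deterministic_per_seed(self):
        a = simulate_references(8, "ITS", seed=5)
        b = simulate_references(8, "ITS", seed=5)
        assert a.sequences == b.sequences
        assert a.lineages == b.lineages
        c = simulate_references(8, "ITS", seed=6)
        assert c.sequences != a.sequences

    def test_insert_lengths_within_marker_range(self):
        for marker in ("16S", "ITS"):
            refs = simulate_references(12, marker, seed=2)
            lo, hi = INSERT_RANGES[marker]
            for seq in refs.sequences.values():
                assert lo <= len(seq) <= hi

    def test_sister_taxa_more_similar_than_distant_taxa(self):
        refs = simulate_references(14, "16S", seed=9)
        ids = refs.ids

        def lineage_overlap(a, b):
            ra, rb = refs.lineages[a].ranks, refs.lineages[b].ranks
            d = 0
            while d < min(len(ra), len(rb)) and ra[d] == rb[d]:
                d += 1
            return d

        def identity(a, b):
            sa, sb = refs.sequences[a], refs.sequences[b]
            d = edlib.align(sa, sb, mode="NW", task="distance")["editDistance"]
            return 1 - d / max(len(sa), len(sb))

        pairs = [
            (lineage_overlap(a, b), identity(a, b))
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        ]
        overlaps = sorted({o for o, _ in pairs})
        assert len(overlaps) >= 2
        sisters = [i for o, i in pairs if o == overlaps[-1]]
        distant = [i for o, i in pairs if o == overlaps[0]]
        assert np.mean(sisters) > np.mean(distant)


@pytest.fixture(scope="module")
def refs():
    return simulate_references(12, "16S", seed=4)


class TestSimulateCommunity:

    def test_proportions_are_simplex(self, refs):
        for kind in ("raw", "sterilized", "post_treatment"):
            p = simulate_community(refs, kind, seed=1).proportions
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert (p >= 0).all()

    def test_sterilized_has_at_most_three_taxa(self, refs):
        for seed in range(10):
            prof = simulate_community(refs, "sterilized", seed=seed)
            assert (prof.proportions > 0).sum() <= 3
            assert prof.relative_yield < 1.0

    def test_raw_more_diverse_than_post_treatment_on_average(self, refs):
        raw_s = [
            shannon(simulate_community(refs, "raw", seed=s).proportions)
            for s in range(20)
        ]
        post_s = [
            shannon(simulate_community(refs, "post_treatment", seed=s).proportions)
            for s in range(20)
        ]
        assert np.mean(raw_s) > np.mean(post_s)

    def test_unknown_kind_rejected(self, refs):
        with pytest.raises(SimulationError):
            simulate_community(refs, "boiled", seed=0)


@pytest.fixture(scope="module")
def setup():
    cfg = DesignConfig(
        single_containers=("I",), double_containers=(),
        times=("A",), n_leaf_samples=0, markers=("16S",),
    )
    plans = expand_design(cfg)
    refs = simulate_references(6, "16S", seed=3)
    profiles = {
        "A-I": simulate_community(refs, "raw", seed=0, sample_id="A-I")
    }
    return {"16S": refs}, profiles, plans


class TestSimulateReads:

    def test_deterministic_given_seed(self, setup):
        refsets, profiles, plans = setup
        r1, t1 = simulate_reads(refsets, profiles, plans, 20, seed=8)
        r2, t2 = simulate_reads(refsets, profiles, plans, 20, seed=8)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert t1.equals(t2)

    def test_truth_has_one_row_per_read(self, setup):
        refsets, profiles, plans = setup
        reads, truth = simulate_reads(refsets, profiles, plans, 15, seed=2)
        assert len(truth) == len(reads)
        assert list(truth.read_id) == [r.read_id for r in reads]

    def test_error_free_read_structure(self, setup):
        refsets, profiles, plans = setup
        reads, truth = simulate_reads(
            refsets, profiles, plans, 10,
            {"sub": 0, "ins": 0, "del": 0}, seed=1,
        )
        refs = refsets["16S"]
        for read, row in zip(reads, truth.itertuples()):
            insert = refs.sequences[row.reference_id]
            plan = next(p for p in plans if p.library_id == row.library_id)
            expected = len(insert) + len(plan.forward_primer) + len(
                plan.reverse_primer
            )
            assert len(read) == expected
            assert row.n_errors == 0

    def test_both_strands_emitted(self, setup):
        refsets, profiles, plans = setup
        _, truth = simulate_reads(refsets, profiles, plans, 40, seed=6)
        assert set(truth.strand) == {"+", "-"}

    def test_expected_length_under_indels(self, setup):
        """E[read length] = clean length * (1 + ins - del), Monte-Carlo."""
        refsets, profiles, plans = setup
        rates = {"sub": 0.0, "ins": 0.06, "del": 0.02}
        reads, truth = simulate_reads(
            refsets, profiles, plans, 300, rates, seed=13,
        )
        refs = refsets["16S"]
        primer_len = {
            p.library_id: len(p.forward_primer) + len(p.reverse_primer)
            for p in plans
        }
        clean = np.array([
            len(refs.sequences[row.reference_id]) + primer_len[row.library_id]
            for row in truth.itertuples()
        ])
        observed = np.array([len(r) for r in reads])
        ratio = observed.sum() / clean.sum()
        assert ratio == pytest.approx(1 + 0.06 - 0.02, abs=0.005)

    def test_invalid_rates_rejected(self, setup):
        refsets, profiles, plans = setup
        with pytest.raises(SimulationError):
            simulate_reads(refsets, profiles, plans, 5,
                           {"sub": 0.5, "ins": 0.4, "del": 0.2})
        with pytest.raises(SimulationError):
            simulate_reads(refsets, profiles, plans, 5, chimera_rate=1.0)
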