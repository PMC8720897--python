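import numpy as np
import pytest

from minitag.align import revcomp
from minitag.demux import (
    DemuxConfigError,
    PrimerHit,
    align_primer,
    classify_read,
    demux_pool,
    filter_hits,
    validate_windows,
)
from minitag.io_formats import Read

from conftest import make_pool


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def amplicon_read(rng, plan, insert_len, read_id="r1", flip=False):
    """Error-free read for a library plan with a random insert."""
    fwd = plan.forward_primer.full_sequence.replace("M", "A")
    rev = plan.reverse_primer.full_sequence.replace("M", "A")
    seq = fwd + random_dna(rng, insert_len) + revcomp(rev)
    if flip:
        seq = revcomp(seq)
    return Read(read_id, seq)


@pytest.fixture()
def lib16s_r1(small_plans):
    return next(p for p in small_plans if p.marker == "16S" and p.round == 1)


@pytest.fixture()
def lib16s_r2(small_plans, lib16s_r1):
    return next(
        p for p in small_plans
        if p.marker == "16S" and p.round == 2
        and p.sample_id == lib16s_r1.sample_id
    )


class TestAlignPrimer:
    def test_exact_embedding_at_offset(self, rng, lib16s_r1):
        primer = lib16s_r1.forward_primer
        embedded = primer.full_sequence.replace("M", "C")
        read = Read("r1", random_dna(rng, 5) + embedded + random_dna(rng, 60))
        hits = align_primer(primer, read)
        top = hits[0]
        assert top.strand == "plus"
        assert top.primer_coverage == 1.0
        assert top.read_start == 5
        assert top.read_end == 5 + len(primer)

    def test_strand_symmetry(self, rng, lib16s_r1):
        primer = lib16s_r1.forward_primer
        embedded = primer.full_sequence.replace("M", "C")
        fwd_read = random_dna(rng, 5) + embedded + random_dna(rng, 60)
        rc_read = Read("r1", revcomp(fwd_read))
        hits = align_primer(primer, rc_read)
        top = hits[0]
        L = len(fwd_read)
        assert top.strand == "minus"
        assert (top.read_start, top.read_end) == (L - 5 - len(primer), L - 5)
        assert top.primer_coverage == 1.0

    def test_no_hit_gives_empty_list(self, lib16s_r1):
        read = Read("r1", "T" * 200)
        assert align_primer(lib16s_r1.forward_primer, read) == []


class TestFilterHits:
    def _hit(self, covered, total):
        return PrimerHit(
            primer_name="p", read_id="r", strand="plus", read_start=0,
            read_end=covered, primer_coverage=covered / total,
            raw_score=covered, bitscore=covered,
        )

    def test_boundary_inclusive_at_090(self):
        kept = filter_hits([self._hit(40, 44)])  # 0.909
        assert len(kept) == 1
        dropped = filter_hits([self._hit(39, 44)])  # 0.886
        assert dropped == []

    def test_empty(self):
        assert filter_hits([]) == []


class TestClassifyRead:
    def test_error_free_assignment_and_trim_length(self, rng, small_plans, lib16s_r1):
        insert_len = 1450 - len(lib16s_r1.forward_primer) - len(
            lib16s_r1.reverse_primer
        )
        read = amplicon_read(rng, lib16s_r1, insert_len)
        rec = classify_read(read, small_plans)
        assert rec.status == "assigned"
        assert rec.library_id == lib16s_r1.library_id
        assert len(rec.trimmed_sequence) == 1450 - 44 - 43

    def test_flipped_read_recovers_same_insert(self, rng, small_plans, lib16s_r1):
        fwd = lib16s_r1.forward_primer.full_sequence.replace("M", "A")
        rev = lib16s_r1.reverse_primer.full_sequence
        insert = random_dna(rng, 1300)
        plus = Read("p", fwd + insert + revcomp(rev))
        minus = Read("m", revcomp(plus.sequence))
        rec_p = classify_read(plus, small_plans)
        rec_m = classify_read(minus, small_plans)
        assert rec_p.status == rec_m.status == "assigned"
        assert rec_p.trimmed_sequence == insert
        assert rec_m.trimmed_sequence == insert

    def test_mixed_tags_are_barcode_mismatch(self, rng, small_plans):
        libs16 = [p for p in small_plans if p.marker == "16S" and p.round == 1]
        a, b = libs16[0], libs16[1]
        fwd = a.forward_primer.full_sequence.replace("M", "A")
        rev = b.reverse_primer.full_sequence
        read = Read("chim", fwd + random_dna(rng, 1300) + revcomp(rev))
        rec = classify_read(read, small_plans)
        assert rec.status == "barcode_mismatch"

    def test_short_16s_read_is_length_fail(self, rng, small_plans, lib16s_r1):
        read = amplicon_read(rng, lib16s_r1, 1100 - 87)
        assert len(read) == 1100
        rec = classify_read(read, small_plans)
        assert rec.status == "length_fail"

    def test_missing_reverse_primer(self, rng, small_plans, lib16s_r1):
        fwd = lib16s_r1.forward_primer.full_sequence.replace("M", "A")
        read = Read("r1", fwd + random_dna(rng, 1300))
        rec = classify_read(read, small_plans)
        assert rec.status == "no_reverse_hit"

    def test_no_primer_at_all(self, rng, small_plans):
        rec = classify_read(Read("r1", random_dna(rng, 1400)), small_plans)
        assert rec.status == "no_forward_hit"


class TestRoundDiscrimination:
    def test_round2_primer_covers_63_percent_of_round1_read(
        self, rng, lib16s_r1, lib16s_r2
    ):
        """A round-1 read aligned by its round-2 primer covers only 44/70."""
        read = amplicon_read(rng, lib16s_r1, 1350)
        hits = align_primer(lib16s_r2.forward_primer, read)
        top = hits[0]
        assert top.primer_coverage == pytest.approx(44 / 70)
        assert top.primer_coverage < 0.90

    def test_round_correct_assignment_both_ways(
        self, rng, small_plans, lib16s_r1, lib16s_r2
    ):
        for plan in (lib16s_r1, lib16s_r2):
            for flip in (False, True):
                read = amplicon_read(rng, plan, 1300, flip=flip)
                rec = classify_read(read, small_plans)
                assert rec.status == "assigned"
                assert rec.library_id == plan.library_id


class TestDemuxPool:
    def test_error_free_pool_fully_and_correctly_assigned(
        self, clean_pool, small_plans, ref_sets
    ):
        reads, truth = clean_pool
        records, summary = demux_pool(reads, small_plans)
        assert summary.status_counts["assigned"] == len(reads)
        truth_lib = dict(zip(truth.read_id, truth.library_id))
        for rec in records:
            assert rec.library_id == truth_lib[rec.read_id]

    def test_trimming_is_exact_on_both_strands(
        self, clean_pool, small_plans, ref_sets
    ):
        reads, truth = clean_pool
        records, _ = demux_pool(reads, small_plans)
        by_id = {r.read_id: r for r in records}
        seen_strands = set()
        for row in truth.itertuples():
            rec = by_id[row.read_id]
            expected = ref_sets[row.marker].sequences[row.reference_id]
            assert rec.trimmed_sequence == expected
            seen_strands.add(row.strand)
        assert seen_strands == {"+", "-"}

    def test_conservation_under_noise(
        self, ref_sets, raw_profiles, small_plans
    ):
        reads, _ = make_pool(
            ref_sets, raw_profiles, small_plans, 10,
            {"sub": 0.05, "ins": 0.04, "del": 0.04}, 0.02, seed=77,
        )
        records, summary = demux_pool(reads, small_plans)
        assert sum(summary.status_counts.values()) == len(reads)
        assert len(records) == len(reads)

    def test_chimeras_are_barcode_mismatch(
        self, ref_sets, raw_profiles, small_plans
    ):
        reads, truth = make_pool(
            ref_sets, raw_profiles, small_plans, 30,
            {"sub": 0, "ins": 0, "del": 0}, 0.05, seed=55,
        )
        records, summary = demux_pool(reads, small_plans)
        n_chimera = int(truth.is_chimera.sum())
        assert n_chimera > 0
        assert summary.status_counts["barcode_mismatch"] == n_chimera
        assert summary.status_counts["assigned"] == len(reads) - n_chimera

    def test_empty_primer_sheet_is_config_error(self, clean_pool):
        reads, _ = clean_pool
        with pytest.raises(DemuxConfigError):
            demux_pool(reads[:5], [])

    def test_overlapping_windows_rejected(self):
        with pytest.raises(DemuxConfigError):
            validate_windows({"16S": (1200, 1700), "ITS": (600, 1300)})
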