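import numpy as np
import pytest

from mirtronkit.io_formats import Genome, IntronRecord
from mirtronkit.hairpin_annotation import (
    AnnotationCriteria,
    annotate,
    apply_criteria,
    assess_duplex,
    classify_subtype,
    define_hairpin_extent,
    fold_hairpin,
)
from mirtronkit.mapping import LocusReadSummary, PlacedRead


def _read(s, e, count=10, lib_class="total", suffix="", weight=1.0):
    return PlacedRead(
        sense_start=s, sense_end=e, sequence="N" * (e - s),
        trimmed_suffix=suffix, count=count, weight=weight,
        library_id="L", lib_class=lib_class,
    )


def _intron(length=100, strand="+"):
    return IntronRecord("c", 1000, 1000 + length, strand, "G", 1, 1)


class TestHairpinExtent:
    def test_splice_flush_reads_give_whole_intron(self):
        intron = _intron(80)
        summ = LocusReadSummary(intron, reads=[_read(0, 22, 100), _read(58, 80, 30)])
        b = define_hairpin_extent(intron, summ)
        assert b.hairpin == (0, 80)
        assert len(b.fivep) == 1 and len(b.threep) == 1

    def test_snapping_within_one_nt_of_splice_sites(self):
        intron = _intron(80)
        summ = LocusReadSummary(intron, reads=[_read(1, 23, 100), _read(57, 79, 30)])
        b = define_hairpin_extent(intron, summ)
        assert b.hairpin == (0, 80)

    def test_internal_dominant_5p_start_defines_extent(self):
        intron = _intron(215)
        summ = LocusReadSummary(
            intron, reads=[_read(150, 172, 100), _read(193, 215, 30)]
        )
        b = define_hairpin_extent(intron, summ)
        assert b.hairpin == (150, 215)

    def test_tie_breaks_to_lower_coordinate(self):
        intron = _intron(120)
        summ = LocusReadSummary(
            intron,
            reads=[_read(10, 32, 50), _read(12, 34, 50), _read(90, 112, 20)],
        )
        b = define_hairpin_extent(intron, summ)
        assert b.hairpin[0] == 10

    def test_single_stack_cannot_form_duplex(self):
        intron = _intron(100)
        summ = LocusReadSummary(intron, reads=[_read(0, 22, 500)])
        assert define_hairpin_extent(intron, summ) is None

    def test_loop_reads_bucketed_between_arms(self):
        intron = _intron(90)
        summ = LocusReadSummary(
            intron,
            reads=[_read(0, 22, 100), _read(68, 90, 30), _read(25, 45, 10)],
        )
        b = define_hairpin_extent(intron, summ)
        assert len(b.loop) == 1

    def test_control_ip_reads_do_not_drive_extent(self):
        intron = _intron(100)
        summ = LocusReadSummary(
            intron,
            reads=[
                _read(0, 22, 5),
                _read(78, 100, 5),
                _read(40, 60, 10000, lib_class="control_ip"),
            ],
        )
        b = define_hairpin_extent(intron, summ)
        assert b.hairpin == (0, 100)


class TestClassifySubtype:
    @pytest.mark.parametrize(
        "hairpin,expected",
        [
            ((0, 100), "conventional"),
            ((1, 99), "conventional"),  # within splice tolerance
        ],
    )
    def test_hairpin_spanning_intron_is_conventional(self, hairpin, expected):
        intron = _intron(100)
        subtype, amb = classify_subtype(intron, hairpin)
        assert subtype == expected
        assert amb is False

    def test_5p_tailed_hairpin_at_acceptor(self):
        intron = _intron(260)
        subtype, amb = classify_subtype(intron, (200, 260))
        assert (subtype, amb) == ("5p_tailed", False)

    def test_3p_tailed_hairpin_at_donor(self):
        intron = _intron(260)
        subtype, amb = classify_subtype(intron, (0, 60))
        assert (subtype, amb) == ("3p_tailed", False)

    def test_two_tailed_ends_far_from_both_sites(self):
        intron = _intron(160)
        subtype, amb = classify_subtype(intron, (30, 130))
        assert (subtype, amb) == ("two_tailed", False)

    def test_ambiguous_band_resolves_to_nearest_and_flags(self):
        intron = _intron(100)
        # 5' offset 2: in (1, 5), nearer abutting -> conventional, flagged
        subtype, amb = classify_subtype(intron, (2, 100))
        assert (subtype, amb) == ("conventional", True)
        # 5' offset 4: nearer free -> 5p_tailed, flagged
        subtype, amb = classify_subtype(intron, (4, 100))
        assert (subtype, amb) == ("5p_tailed", True)

    def test_hairpin_outside_intron_rejected(self):
        with pytest.raises(ValueError):
            classify_subtype(_intron(50), (0, 60))


def _planted_buckets_and_fold(overhang=2):
    """A perfect 20-bp stem with configurable 3' overhangs at both ends."""
    arm = "GCGGAUGCCGGAUCGGCAGC".replace("U", "T")
    comp = arm.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    # pairing plan: fivep[0..19] with threep positions shifted by overhang
    fivep = arm + "A" * overhang
    threep = comp + "C" * overhang
    seq = fivep + "AAAA" + threep
    fold = fold_hairpin(seq)
    from mirtronkit.hairpin_annotation import ArmBuckets

    n = len(seq)
    b = ArmBuckets(
        hairpin=(0, n),
        fivep_interval=(0, len(fivep)),
        threep_interval=(n - len(threep), n),
    )
    return fold, b


class TestAssessDuplex:
    def test_two_nt_overhangs_accepted(self):
        fold, b = _planted_buckets_and_fold(overhang=2)
        geom, ok, reason = assess_duplex(fold, b)
        assert geom.overhang_open_end == 2
        assert geom.overhang_dicer_end == 2
        assert ok, reason

    def test_blunt_duplex_within_window(self):
        fold, b = _planted_buckets_and_fold(overhang=0)
        geom, ok, _ = assess_duplex(fold, b)
        assert (geom.overhang_open_end, geom.overhang_dicer_end) == (0, 0)
        assert ok

    def test_six_nt_overhang_rejected(self):
        fold, b = _planted_buckets_and_fold(overhang=6)
        geom, ok, reason = assess_duplex(fold, b)
        assert not ok
        assert reason == "overhang_outside_window"

    def test_unpaired_arms_rejected(self):
        seq = "A" * 50
        fold = fold_hairpin(seq)
        from mirtronkit.hairpin_annotation import ArmBuckets

        b = ArmBuckets(hairpin=(0, 50), fivep_interval=(0, 22),
                       threep_interval=(28, 50))
        _, ok, reason = assess_duplex(fold, b)
        assert not ok
        assert reason == "arms_not_paired_in_stem"


class TestApplyCriteria:
    def test_duplex_criterion_exact_threshold(self):
        assert apply_criteria(45, 5, 0, 50, True) == "confident_duplex"

    def test_agoip_criterion(self):
        assert apply_criteria(100, 1, 20, 101, True) == "confident_agoip"

    def test_below_all_thresholds_is_candidate(self):
        assert apply_criteria(45, 4, 0, 49, True) == "candidate"

    def test_dicing_failure_blocks_confident_tiers(self):
        assert apply_criteria(200, 50, 50, 250, False) == "candidate"

    def test_rescue_a(self):
        assert apply_criteria(30, 3, 20, 40, True) == "rescue_a"

    def test_rescue_b(self):
        assert apply_criteria(80, 4, 10, 100, True) == "rescue_b"

    def test_rejected_under_ten_total(self):
        assert apply_criteria(5, 1, 0, 9, True) == "rejected"

    def test_weighted_counts_rounded_half_up(self):
        # 49.5 duplex rounds to 50
        assert apply_criteria(45.0, 4.5, 0, 50, True) == "confident_duplex"
        assert apply_criteria(45.0, 4.4, 0, 50, True) == "candidate"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            apply_criteria(-1, 0, 0, 0, True)


class TestAnnotate:
    def test_empty_library_set_yields_no_calls(self, small_truth):
        summaries = {
            i.locus_id: LocusReadSummary(i) for i in small_truth.introns
        }
        calls = annotate(small_truth.genome, small_truth.introns, summaries)
        assert calls == []

    def test_exactly_49_duplex_reads_stays_candidate(self, small_truth):
        planted = small_truth.mirtrons()[0]
        intron = planted.intron
        h5, h3 = planted.hairpin_in_intron
        m = planted.mature_len
        summ = LocusReadSummary(
            intron,
            reads=[_read(h5, h5 + m, 45), _read(h3 - m, h3, 4)],
        )
        calls = annotate(
            small_truth.genome, [intron], {intron.locus_id: summ}
        )
        assert calls[0].tier == "candidate"
        # one more star read crosses the duplex threshold
        summ2 = LocusReadSummary(
            intron,
            reads=[_read(h5, h5 + m, 45), _read(h3 - m, h3, 5)],
        )
        calls2 = annotate(
            small_truth.genome, [intron], {intron.locus_id: summ2}
        )
        assert calls2[0].tier == "confident_duplex"

    def test_conventional_premirna_length_equals_intron_length(self, small_truth, small_calls):
        truth_map = {p.locus_id: p for p in small_truth.mirtrons()}
        conv = [
            c for c in small_calls
            if c.locus_id in truth_map
            and truth_map[c.locus_id].subtype == "conventional"
        ]
        assert conv
        for c in conv:
            assert c.premirna_length == c.intron.length
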