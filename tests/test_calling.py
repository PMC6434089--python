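"""Threshold calling, karyotype rendering/parsing and concordance scoring."""

import pytest

from sccnv import (CallingConfig, CnvCall, call_cnvs, concordance,
                   parse_karyotype, render_karyotype)
from sccnv.segment import Segment
from sccnv.simulate import cell_line_fixtures, kit_benchmark_calls


def seg(chrom, start, end, mean, n_windows=None):
    n = n_windows or max(1, (end - start) // 20_000)
    return Segment(chrom, 0, n, start, end, mean, n)


class TestCallCnvs:
    @pytest.mark.parametrize("mean,size,expected_kind", [
        (0.40, 5_000_000, "gain"),       # above +0.37, big enough
        (0.30, 50_000_000, None),        # 0.30 <= 0.37: no call however big
        (0.37, 50_000_000, None),        # boundary value does not call
        (-0.90, 3_500_000, None),        # size 3.5 Mb <= 4 Mb: no call
        (-0.90, 4_000_000, None),        # boundary size does not call
        (-0.52, 4_100_000, "loss"),
        (-0.51, 50_000_000, None),       # boundary value does not call
    ])
    def test_threshold_mechanics(self, mean, size, expected_kind):
        calls = call_cnvs([seg("chr1", 0, size, mean)], CallingConfig())
        if expected_kind is None:
            assert calls == []
        else:
            assert len(calls) == 1
            assert calls[0].kind == expected_kind

    def test_adjacent_same_kind_segments_merge_before_size_filter(self):
        segs = [seg("chr1", 0, 3_000_000, 0.5),
                seg("chr1", 3_000_000, 6_000_000, 0.45)]
        calls = call_cnvs(segs, CallingConfig())
        assert len(calls) == 1
        assert calls[0].start_bp == 0 and calls[0].end_bp == 6_000_000
        # neither piece alone passes the 4-Mb filter
        assert call_cnvs(segs[:1], CallingConfig()) == []

    def test_short_neutral_gap_bridged_long_gap_blocks(self):
        # 0.5-Mb dip inside one event: bridged (tolerance min_size/4 = 1 Mb)
        segs = [seg("chr1", 0, 3_000_000, 0.5),
                seg("chr1", 3_000_000, 3_500_000, 0.0),
                seg("chr1", 3_500_000, 6_500_000, 0.5)]
        calls = call_cnvs(segs, CallingConfig())
        assert len(calls) == 1
        assert (calls[0].start_bp, calls[0].end_bp) == (0, 6_500_000)
        # 1.5-Mb gap separates two events; neither passes the size filter
        far = [seg("chr1", 0, 3_000_000, 0.5),
               seg("chr1", 3_000_000, 4_500_000, 0.0),
               seg("chr1", 4_500_000, 7_500_000, 0.5)]
        assert call_cnvs(far, CallingConfig()) == []

    def test_opposite_direction_never_bridged(self):
        segs = [seg("chr1", 0, 3_000_000, 0.5),
                seg("chr1", 3_000_000, 3_200_000, -0.9),
                seg("chr1", 3_200_000, 6_500_000, 0.5)]
        calls = call_cnvs(segs, CallingConfig())
        assert all(c.kind == "gain" or c.size_bp <= 4_000_000 for c in calls)
        assert not any(c.start_bp == 0 and c.end_bp == 6_500_000 for c in calls)

    def test_chry_excluded_by_default(self):
        calls = call_cnvs([seg("chrY", 0, 5_000_000, -2.0)], CallingConfig())
        assert calls == []

    def test_raising_thresholds_monotone(self):
        rng_segs = [seg("chr1", i * 5_000_000, (i + 1) * 5_000_000, m)
                    for i, m in enumerate([0.4, 0.6, -0.7, 0.2, 0.5, -0.55])]
        base = len(call_cnvs(rng_segs, CallingConfig()))
        stricter_gain = len(call_cnvs(rng_segs, CallingConfig(gain_log2=0.55)))
        bigger_min = len(call_cnvs(rng_segs, CallingConfig(min_size_bp=6_000_000)))
        assert stricter_gain <= base
        assert bigger_min <= base


class TestRenderKaryotype:
    def test_whole_chr21_gain_female(self, chrom_lengths):
        calls = [CnvCall("chr21", 0, chrom_lengths["chr21"], "gain", 0.58)]
        assert render_karyotype(calls, "XX", chrom_lengths) == "47,XX,+21"

    def test_whole_x_loss_renders_xo(self, chrom_lengths):
        calls = [CnvCall("chrX", 0, chrom_lengths["chrX"], "loss", -1.0)]
        assert render_karyotype(calls, "XX", chrom_lengths) == "45,XO"

    def test_no_calls(self, chrom_lengths):
        assert render_karyotype([], "XX", chrom_lengths) == "46,XX"

    def test_male_sample_absorbs_expected_x_loss(self, chrom_lengths):
        calls = [CnvCall("chrX", 0, chrom_lengths["chrX"], "loss", -1.0),
                 CnvCall("chr18", 0, chrom_lengths["chr18"], "gain", 0.58)]
        out = render_karyotype(calls, "XX", chrom_lengths, sample_sex="XY")
        assert out == "47,XY,+18"

    def test_partial_deletion_with_band_labels(self, chrom_lengths, band_table):
        lo, hi = band_table.band_span("chr16", "p12.1", "p11.2")
        calls = [CnvCall("chr16", lo, hi, "loss", -1.0)]
        out = render_karyotype(calls, "XX", chrom_lengths, band_table=band_table)
        assert out == "46,XX, del(16p12.1-p11.2)"

    def test_partial_without_band_table_uses_mb(self, chrom_lengths):
        calls = [CnvCall("chr21", 0, 1_000_000, "gain", 0.6)]
        out = render_karyotype(calls, "XX", chrom_lengths)
        assert out == "46,XX, dup(21:0.00-1.00Mb)"

    def test_residual_partial_absorbed_into_whole_chrom_event(self, chrom_lengths):
        L = chrom_lengths["chr13"]
        calls = [CnvCall("chr13", 0, int(0.85 * L), "gain", 0.6),
                 CnvCall("chr13", int(0.9 * L), L, "gain", 0.55)]
        assert render_karyotype(calls, "XY", chrom_lengths) == "47,XY,+13"


class TestParseKaryotype:
    def test_round_trip_through_rendering(self, chrom_lengths, band_table):
        lo, hi = band_table.band_span("chr4", "p16.3", "p16.2")
        calls = [CnvCall("chr4", lo, hi, "loss", -1.0),
                 CnvCall("chr21", 0, chrom_lengths["chr21"], "gain", 0.6)]
        text = render_karyotype(calls, "XX", chrom_lengths, band_table=band_table)
        back = parse_karyotype(text, chrom_lengths, band_table)
        assert {(c.chrom, c.start_bp, c.end_bp, c.kind) for c in back} == \
               {(c.chrom, c.start_bp, c.end_bp, c.kind) for c in calls}

    def test_xo_and_minus_tokens(self, chrom_lengths):
        events = parse_karyotype("+21, −22", chrom_lengths)  # unicode minus
        assert {(c.chrom, c.kind) for c in events} == \
               {("chr21", "gain"), ("chr22", "loss")}
        xo = parse_karyotype("45,XO", chrom_lengths)
        assert [(c.chrom, c.kind) for c in xo] == [("chrX", "loss")]


class TestConcordance:
    def test_self_concordance_perfect(self, chrom_lengths, band_table):
        fixtures = dict(cell_line_fixtures())
        for name, spec in fixtures.items():
            calls = spec.expected_calls(chrom_lengths)
            res = concordance(calls, spec, chrom_lengths, band_table=band_table)
            assert (res.n_false_positive, res.n_false_negative) == (0, 0)

    def test_direction_must_match(self, chrom_lengths):
        det = [CnvCall("chr21", 0, chrom_lengths["chr21"], "loss", -1.0)]
        conf = [CnvCall("chr21", 0, chrom_lengths["chr21"], "gain", 0.6)]
        res = concordance(det, conf, chrom_lengths)
        assert (res.n_true_positive, res.n_false_positive,
                res.n_false_negative) == (0, 1, 1)

    def test_reciprocal_overlap_threshold(self, chrom_lengths):
        conf = [CnvCall("chr1", 0, 2_000_000, "loss", 0.0)]
        barely = [CnvCall("chr1", 900_000, 2_900_000, "loss", 0.0)]  # 55% RO
        res = concordance(barely, conf, chrom_lengths)
        assert res.n_true_positive == 1
        disjointish = [CnvCall("chr1", 1_500_000, 3_500_000, "loss", 0.0)]  # 25%
        res = concordance(disjointish, conf, chrom_lengths)
        assert res.n_true_positive == 0

    def test_benchmark_genomeplex_false_positives(self, chrom_lengths, band_table):
        """GenomePlex detects everything plus exactly two extra events."""
        fixtures = dict(cell_line_fixtures())
        table = kit_benchmark_calls()
        totals = {"TP": 0, "FP": 0, "FN": 0}
        for line, detected in table["GenomePlex"].items():
            res = concordance(detected, fixtures[line], chrom_lengths,
                              band_table=band_table)
            totals["TP"] += res.n_true_positive
            totals["FP"] += res.n_false_positive
            totals["FN"] += res.n_false_negative
        assert totals["FP"] == 2
        assert totals["FN"] == 0

    def test_benchmark_malbac_picoplex_fully_concordant(self, chrom_lengths,
                                                        band_table):
        fixtures = dict(cell_line_fixtures())
        table = kit_benchmark_calls()
        for kit in ("MALBAC", "PicoPLEX"):
            for line, detected in table[kit].items():
                res = concordance(detected, fixtures[line], chrom_lengths,
                                  band_table=band_table)
                assert res.n_false_positive == 0
                assert res.n_false_negative == 0

    def test_benchmark_mda_gm00857_all_wrong(self, chrom_lengths, band_table):
        """MDA on the 45,XO line: two spurious calls, monosomy X missed."""
        fixtures = dict(cell_line_fixtures())
        detected = kit_benchmark_calls()["MDA"]["GM00857"]
        res = concordance(detected, fixtures["GM00857"], chrom_lengths,
                          band_table=band_table)
        assert (res.n_true_positive, res.n_false_positive,
                res.n_false_negative) == (0, 2, 1)


class TestFixtures:
    def test_seven_specs(self):
        assert len(cell_line_fixtures()) == 7

    def test_gm01183_one_loss_one_gain(self):
        spec = dict(cell_line_fixtures())["GM01183"]
        kinds = sorted((c, cn) for c, _s, _e, cn in spec.events)
        assert len(spec.events) == 2
        assert {cn for _c, cn in kinds} == {1, 3}

    def test_gm00857_monosomy_x(self):
        spec = dict(cell_line_fixtures())["GM00857"]
        assert spec.sex == "XO"
        assert spec.copy_number("chrX") == 1
        assert spec.copy_number("chr5") == 2
        assert spec.events == []
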