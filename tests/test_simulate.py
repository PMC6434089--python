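"""Simulator determinism, expectation correctness and calibration."""

import numpy as np
import pytest

from sccnv import (KIT_PROFILES, KaryotypeSpec, KitNoiseProfile,
                   SimulationConfig, calibrate_bias_sd, mapd,
                   normalize_counts, repeat_correlation, simulate_counts)
from sccnv.counts import aggregate_counts
from sccnv.errors import CalibrationError
from sccnv.grid import aggregate_grid
from sccnv.qc import MAPD_IID_FACTOR, coverage_uniformity
from sccnv.simulate import _simulated_mapd, copy_number_track


def mapd_at_100kb(sample, control, grid):
    agg = aggregate_grid(grid, 5)
    s = aggregate_counts(sample, grid, 5, agg_grid=agg)
    k = aggregate_counts(control, grid, 5, agg_grid=agg)
    return mapd(normalize_counts(s, k, agg))


class TestSimulateCounts:
    def test_deterministic_given_seed(self, scaled_grid):
        cfg = dict(karyotype=KaryotypeSpec(sex="XX"),
                   kit_profile=KIT_PROFILES["MALBAC"], grid=scaled_grid,
                   mean_reads_per_window=30.0, seed=17)
        a = simulate_counts(SimulationConfig(**cfg))
        b = simulate_counts(SimulationConfig(**cfg))
        np.testing.assert_array_equal(a.sample.counts, b.sample.counts)
        np.testing.assert_array_equal(a.control.counts, b.control.counts)
        c = simulate_counts(SimulationConfig(**{**cfg, "seed": 18}))
        assert not np.array_equal(a.sample.counts, c.sample.counts)

    def test_expectation_mode_trisomy_exact(self, scaled_grid):
        spec = KaryotypeSpec(sex="XX", events=[
            ("chr21", 0, scaled_grid.chrom_lengths["chr21"], 3)])
        res = simulate_counts(SimulationConfig(
            karyotype=spec, kit_profile=KitNoiseProfile("none", 0.0),
            grid=scaled_grid, seed=1, expectation_mode=True,
            genomic_bias_sd_log2=0.0))
        prof = normalize_counts(res.sample, res.control, scaled_grid)
        sl = scaled_grid.chrom_slices["chr21"]
        ok = ~prof.mask
        on21 = np.zeros(scaled_grid.n_windows, bool)
        on21[sl] = True
        np.testing.assert_allclose(prof.ratio[ok & on21], 1.5, rtol=1e-6)
        np.testing.assert_allclose(prof.ratio[ok & ~on21], 1.0, rtol=1e-6)

    def test_mean_ratio_converges_to_copy_number(self, scaled_grid):
        """Averaged over seeds, the bias-free ratio converges to CN/2."""
        spec = KaryotypeSpec(sex="XX", events=[
            ("chr21", 0, scaled_grid.chrom_lengths["chr21"], 3)])
        sl = scaled_grid.chrom_slices["chr21"]
        means = []
        for seed in range(20):
            res = simulate_counts(SimulationConfig(
                karyotype=spec, kit_profile=KitNoiseProfile("none", 0.0),
                grid=scaled_grid, mean_reads_per_window=100.0, seed=seed))
            prof = normalize_counts(res.sample, res.control, scaled_grid)
            means.append(np.nanmean(prof.ratio[sl]))
        assert np.mean(means) == pytest.approx(1.5, abs=0.03)

    def test_copy_number_track_sex_handling(self, scaled_grid):
        cn_xy = copy_number_track(KaryotypeSpec(sex="XY"), scaled_grid)
        cn_xo = copy_number_track(KaryotypeSpec(sex="XO"), scaled_grid)
        cn_xx = copy_number_track(KaryotypeSpec(sex="XX"), scaled_grid)
        slx = scaled_grid.chrom_slices["chrX"]
        assert set(cn_xy[slx]) == {1} and set(cn_xo[slx]) == {1}
        assert set(cn_xx[slx]) == {2}
        assert set(cn_xx[scaled_grid.chrom_slices["chr7"]]) == {2}

    @pytest.mark.parametrize("kit,target", [
        ("PicoPLEX", 0.85), ("MALBAC", 0.88), ("GenomePlex", 0.55)])
    def test_repeat_correlation_matches_kit_target(self, scaled_grid, kit, target):
        """Depth-normalized repeat profiles reach the calibrated Pearson r."""
        vals = []
        for seed in (31, 32, 33):
            res = simulate_counts(SimulationConfig(
                karyotype=KaryotypeSpec(sex="XX"),
                kit_profile=KIT_PROFILES[kit], grid=scaled_grid,
                mean_reads_per_window=30.0, seed=seed, n_repeats=2))
            vals.append(repeat_correlation(res.samples, scaled_grid))
        assert np.mean(vals) == pytest.approx(target, abs=0.05)

    def test_mda_repeats_essentially_uncorrelated(self, scaled_grid):
        res = simulate_counts(SimulationConfig(
            karyotype=KaryotypeSpec(sex="XX"),
            kit_profile=KIT_PROFILES["MDA"], grid=scaled_grid,
            mean_reads_per_window=30.0, seed=41, n_repeats=2))
        assert abs(repeat_correlation(res.samples, scaled_grid)) < 0.08

    def test_genomic_wave_cancels_in_control_normalized_ratio(self, scaled_grid):
        """The genome-intrinsic coverage track never reaches CNV calling."""
        from sccnv import genomic_wave

        from sccnv import normalize_to_control

        wave = genomic_wave(scaled_grid)
        assert np.ptp(wave) > 0.5  # the track is substantial...
        res = simulate_counts(SimulationConfig(
            karyotype=KaryotypeSpec(sex="XX"),
            kit_profile=KitNoiseProfile("none", 0.0), grid=scaled_grid,
            seed=3, expectation_mode=True))
        prof = normalize_to_control(res.sample.counts, res.control.counts,
                                    scaled_grid)
        # ...yet expectation-mode ratios are exactly flat
        np.testing.assert_allclose(prof.ratio[~prof.mask], 1.0, rtol=1e-9)


class TestKitNoiseRanking:
    def test_mapd_ordering_matches_kit_ranking(self, scaled_grid):
        """bulk < PicoPLEX < MALBAC < GenomePlex < MDA on matched seeds."""
        order = ["bulk", "PicoPLEX", "MALBAC", "GenomePlex", "MDA"]
        for seed in (51, 52, 53):
            vals = []
            for kit in order:
                res = simulate_counts(SimulationConfig(
                    karyotype=KaryotypeSpec(sex="XX"),
                    kit_profile=KIT_PROFILES[kit], grid=scaled_grid,
                    mean_reads_per_window=30.0, seed=seed))
                vals.append(mapd_at_100kb(res.sample, res.control, scaled_grid))
            assert vals == sorted(vals), (seed, dict(zip(order, vals)))

    def test_mda_fails_both_qc_rules(self, scaled_grid):
        res = simulate_counts(SimulationConfig(
            karyotype=KaryotypeSpec(sex="XX"), kit_profile=KIT_PROFILES["MDA"],
            grid=scaled_grid, mean_reads_per_window=30.0, seed=61))
        assert mapd_at_100kb(res.sample, res.control, scaled_grid) > 0.4
        assert coverage_uniformity(res.sample, scaled_grid) < 0.90


class TestCalibration:
    def test_target_zero_at_high_depth_gives_zero_sigma(self, scaled_grid):
        """At very high depth the Poisson floor vanishes, so sigma -> 0."""
        s = calibrate_bias_sd(0.01, 5000.0, scaled_grid, seed=5, n_seeds=2)
        assert s == pytest.approx(0.0, abs=0.02)

    def test_inverts_closed_form_at_high_depth(self, scaled_grid):
        """Target 0.9539*0.3 with iid bias recovers sigma ~= 0.3."""
        template = KitNoiseProfile("iid", 0.0, autocorr=0.0)
        target = 0.3 * MAPD_IID_FACTOR
        s = calibrate_bias_sd(target, 5000.0, scaled_grid, seed=6,
                              kit_template=template, n_seeds=2)
        # aggregation of iid bias over 5 windows divides variance by 5
        assert s == pytest.approx(0.3 * np.sqrt(5), rel=0.1)

    def test_target_below_poisson_floor_rejected(self, scaled_grid):
        with pytest.raises(CalibrationError, match="floor"):
            calibrate_bias_sd(0.02, 30.0, scaled_grid, seed=7, n_seeds=2)

    @pytest.mark.parametrize("kit,target,depth,tol", [
        ("bulk", 0.20, 30.0, 0.03),
        ("PicoPLEX", 0.24, 30.0, 0.05),
        ("MALBAC", 0.31, 30.0, 0.04),
        ("GenomePlex", 0.42, 30.0, 0.05),
    ])
    def test_round_trip_reproduces_kit_targets(self, scaled_grid, kit, target,
                                               depth, tol):
        s = calibrate_bias_sd(target, depth, scaled_grid, seed=8,
                              kit_template=KIT_PROFILES[kit], n_seeds=3)
        agg = aggregate_grid(scaled_grid, 5)
        from dataclasses import replace
        m = _simulated_mapd(replace(KIT_PROFILES[kit], bias_sd_log2=s), depth,
                            scaled_grid, agg, 5, [71, 72, 73, 74, 75])
        assert m == pytest.approx(target, abs=tol)

    def test_mda_target_needs_depth_headroom(self, scaled_grid):
        """2.48 is beyond the log-ratio range at 30 reads/window (the
        zero-masking ceiling), but calibrates at 60 reads/window."""
        with pytest.raises(CalibrationError, match="unreachable"):
            calibrate_bias_sd(2.48, 30.0, scaled_grid, seed=9,
                              kit_template=KIT_PROFILES["MDA"], n_seeds=2)
        s = calibrate_bias_sd(2.48, 60.0, scaled_grid, seed=9,
                              kit_template=KIT_PROFILES["MDA"], n_seeds=3)
        agg = aggregate_grid(scaled_grid, 5)
        from dataclasses import replace
        m = _simulated_mapd(replace(KIT_PROFILES["MDA"], bias_sd_log2=s), 60.0,
                            scaled_grid, agg, 5, [81, 82, 83, 84, 85])
        assert m == pytest.approx(2.48, abs=0.15)
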