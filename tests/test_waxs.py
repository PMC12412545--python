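"""WAXS reduction, background/peak fitting, and the closed-form crystal
metrics (Bragg spacing, Scherrer size, crystallinity index)."""

import math

import numpy as np
import pytest

from pellimetrics import synthetic_data as sd
from pellimetrics import waxs


class TestClosedForms:
    def test_bragg_spacing_values(self):
        assert waxs.bragg_spacing(2.0 * math.pi) == pytest.approx(1.0, rel=1e-12)
        assert waxs.bragg_spacing(1.0) == pytest.approx(6.283185307179586, rel=1e-12)

    def test_bragg_spacing_from_cellulose_main_reflection(self):
        # 2θ = 22.7°, λ = 1.54 Å: q = 4π sin(11.35°)/1.54, d = 2π/q ≈ 3.91 Å
        q = float(waxs.twotheta_to_q(22.7, 1.54))
        expected = 1.54 / (2.0 * math.sin(math.radians(11.35)))  # classical λ/(2 sinθ)
        assert waxs.bragg_spacing(q) == pytest.approx(expected, rel=1e-9)
        assert waxs.bragg_spacing(q) == pytest.approx(3.91, abs=0.01)

    def test_bragg_rejects_nonpositive_q(self):
        with pytest.raises(ValueError):
            waxs.bragg_spacing(0.0)

    def test_scherrer_at_zero_angle(self):
        tau = waxs.scherrer_size(math.degrees(0.0154), 0.0, wavelength_A=1.54, K=0.94)
        assert tau == pytest.approx(9.400, rel=1e-9)

    def test_scherrer_inverse_proportional_to_width(self):
        t1 = waxs.scherrer_size(0.4, 22.7)
        t2 = waxs.scherrer_size(0.8, 22.7)
        assert t1 == pytest.approx(2.0 * t2, rel=1e-12)

    def test_scherrer_main_reflection_value(self):
        tau = waxs.scherrer_size(0.6, 22.7, wavelength_A=1.54, K=0.94)
        beta = math.radians(0.6)
        expected = 0.94 * 1.54 / (beta * math.cos(math.radians(11.35))) / 10.0
        assert tau == pytest.approx(expected, rel=1e-9)
        assert tau == pytest.approx(14.1, abs=0.05)

    def test_bragg_of_q_monotone_decreasing_in_angle(self):
        angles = np.linspace(1.0, 89.0, 200)
        d = np.array([waxs.bragg_spacing(float(waxs.twotheta_to_q(a))) for a in angles])
        assert np.all(np.diff(d) < 0)

    def test_q_grid_consistency(self):
        d = sd.gen_diffractogram(sd.pattern_with_fraction(0.3), seed=0)
        expected = 4.0 * np.pi * np.sin(np.radians(d.twotheta_deg / 2.0)) / d.wavelength_A
        assert np.allclose(d.q_invA, expected, atol=1e-9)


class TestMergeLineEraser:
    def test_identity_merge(self):
        frame = np.arange(12.0).reshape(3, 4)
        merged = waxs.merge_line_eraser(frame, frame)
        assert np.array_equal(merged, frame)

    def test_complementary_masks_leave_no_invalid_pixels(self):
        a = np.ones((6, 6))
        b = 3.0 * np.ones((6, 6))
        mask_a = np.zeros((6, 6), bool)
        mask_a[:3] = True
        mask_b = ~mask_a
        merged = waxs.merge_line_eraser(a, b, mask_a, mask_b)
        assert not np.isnan(merged).any()
        assert np.all(merged[:3] == 3.0) and np.all(merged[3:] == 1.0)

    def test_doubly_masked_pixels_are_invalid(self):
        a = np.ones((4, 4))
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True
        merged = waxs.merge_line_eraser(a, a, mask, mask)
        assert np.isnan(merged[1, 1]) and np.isfinite(merged).sum() == 15

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            waxs.merge_line_eraser(np.ones((4, 4)), np.ones((4, 5)))

    def test_slit_merge_matches_slit_free_integration(self):
        truth = sd.pattern_with_fraction(0.3)
        d = sd.gen_diffractogram(truth, seed=0)
        geo = waxs.DetectorGeometry()
        clean, _ = sd.gen_detector_image(d, geo, seed=1, shape=(1344, 1344), poisson_noise=False)
        fa, ma = sd.gen_detector_image(d, geo, seed=2, shape=(1344, 1344), slit_rows=(600, 650), poisson_noise=False)
        fb, mb = sd.gen_detector_image(d, geo, seed=3, shape=(1344, 1344), slit_rows=(700, 750), poisson_noise=False)
        merged = waxs.merge_line_eraser(fa, fb, ma, mb)
        ref = waxs.integrate_azimuthal(clean, geo, n_bins=500, twotheta_range=(10.0, 45.0))
        got = waxs.integrate_azimuthal(merged, geo, n_bins=500, twotheta_range=(10.0, 45.0))
        rel = np.abs(got.intensity - ref.intensity) / ref.intensity.max()
        assert rel.max() < 0.01


class TestAzimuthalIntegration:
    GEO = waxs.DetectorGeometry()

    def test_uniform_frame_gives_flat_profile(self):
        frame = np.full((600, 600), 50.0)
        d = waxs.integrate_azimuthal(frame, self.GEO, n_bins=100, twotheta_range=(2.0, 20.0))
        assert d.intensity.std() / d.intensity.mean() < 0.01

    def test_ring_lands_in_the_right_bin(self):
        """A one-pixel-wide ring at 2θ = 22.7° integrates to a peak within one
        bin of 22.7°, matching a directly coded per-pixel binning oracle."""
        geo = self.GEO
        shape = (1344, 1344)
        tth = geo.twotheta_deg_of(shape)
        frame = np.where(np.abs(tth - 22.7) < 0.03, 1000.0, 1.0)
        d = waxs.integrate_azimuthal(frame, geo, n_bins=350, twotheta_range=(10.0, 45.0))
        peak_angle = d.twotheta_deg[np.argmax(d.intensity)]
        bin_width = (45.0 - 10.0) / 350
        assert abs(peak_angle - 22.7) <= bin_width
        # independent oracle: accumulate per pixel with plain loops over bins
        lo, hi, nb = 10.0, 45.0, 350
        idx = ((tth - lo) / (hi - lo) * nb).astype(int)
        inside = (idx >= 0) & (idx < nb)
        sums = np.zeros(nb)
        counts = np.zeros(nb)
        for b in range(nb):
            sel = inside & (idx == b)
            counts[b] = sel.sum()
            sums[b] = frame[sel].sum()
        oracle = sums / np.maximum(counts, 1)
        assert np.allclose(d.intensity, oracle, rtol=1e-9)

    def test_rotation_invariance(self):
        truth = sd.pattern_with_fraction(0.3)
        dd = sd.gen_diffractogram(truth, seed=0)
        frame, _ = sd.gen_detector_image(dd, self.GEO, seed=4, poisson_noise=False)
        d0 = waxs.integrate_azimuthal(frame, self.GEO, n_bins=200, twotheta_range=(10.0, 45.0))
        d90 = waxs.integrate_azimuthal(np.rot90(frame), self.GEO, n_bins=200, twotheta_range=(10.0, 45.0))
        rel = np.abs(d90.intensity - d0.intensity) / d0.intensity.max()
        assert rel.max() < 0.005

    def test_fully_masked_frame_rejected(self):
        frame = np.ones((100, 100))
        with pytest.raises(waxs.IntegrationError):
            waxs.integrate_azimuthal(frame, self.GEO, n_bins=50, mask=np.ones((100, 100), bool))


class TestBackgroundFit:
    def test_peak_free_halo_recovers_near_zero_crystallinity(self):
        for seed in range(3):
            d = sd.gen_diffractogram(sd.pattern_with_fraction(0.0), seed=seed)
            bg = waxs.fit_background(d)
            assert abs(waxs.crystallinity_index(d, bg)) <= 2.0

    def test_zero_background_truth_gives_small_background_area(self):
        d = sd.gen_diffractogram(sd.pattern_with_fraction(1.0), seed=0)
        bg = waxs.fit_background(d)
        m = (d.twotheta_deg >= 10.0) & (d.twotheta_deg <= 45.0)
        area_sample = np.trapezoid(d.intensity[m], d.twotheta_deg[m])
        assert bg.area_background < 0.03 * area_sample

    def test_constant_offset_shifts_background_area(self):
        d = sd.gen_diffractogram(sd.pattern_with_fraction(0.3), seed=1)
        bg0 = waxs.fit_background(d)
        c = 25.0
        shifted = waxs.Diffractogram1D(d.twotheta_deg, d.intensity + c, d.wavelength_A)
        bg1 = waxs.fit_background(shifted)
        width = 35.0
        assert bg1.area_background - bg0.area_background == pytest.approx(c * width, rel=0.05)

    def test_too_coarse_range_fails_with_anchor_error(self):
        grid = np.arange(5.0, 50.0, 0.05)
        d = waxs.Diffractogram1D(grid, np.exp(-(((grid - 22.0) / 8.0) ** 2)))
        with pytest.raises(waxs.BackgroundFitError):
            waxs.fit_background(d, range_deg=(21.0, 24.0))


class TestPeakFit:
    def test_single_gaussian_self_consistency(self):
        grid = np.linspace(10.0, 45.0, 1751)
        sigma = 0.5
        y = 80.0 * np.exp(-0.5 * ((grid - 22.7) / sigma) ** 2)
        d = waxs.Diffractogram1D(grid, y)
        bg = waxs.BackgroundFit("zero", np.array([10.0, 45.0]), np.zeros_like(grid), (10.0, 45.0), 0.0)
        fit = waxs.fit_peaks(d, bg, [22.7])
        assert fit.converged
        peak = fit.peaks[0]
        assert peak.center_deg == pytest.approx(22.7, abs=1e-6)
        fwhm_true = 2.0 * sigma * math.sqrt(2.0 * math.log(2.0))
        assert peak.fwhm_deg == pytest.approx(fwhm_true, rel=1e-4)

    def test_overlapping_peaks_recovered(self):
        truth = sd.pattern_with_fraction(0.5, noise_sd=0.5)
        d = sd.gen_diffractogram(truth, seed=2)
        bg = waxs.fit_background(d)
        fit = waxs.fit_peaks(d, bg, [14.5, 16.8, 22.7, 34.6])
        for peak, (c_true, w_true, _) in zip(fit.peaks, truth.peaks):
            assert peak.center_deg == pytest.approx(c_true, abs=0.05)
            assert peak.fwhm_deg == pytest.approx(w_true, rel=0.08)

    def test_basin_stability_against_offset_init(self):
        grid = np.linspace(10.0, 45.0, 1751)
        y = 60.0 * np.exp(-0.5 * ((grid - 22.7) / 0.5) ** 2)
        d = waxs.Diffractogram1D(grid, y)
        bg = waxs.BackgroundFit("zero", np.array([10.0, 45.0]), np.zeros_like(grid), (10.0, 45.0), 0.0)
        exact = waxs.fit_peaks(d, bg, [22.7]).peaks[0]
        offset = waxs.fit_peaks(d, bg, [23.0]).peaks[0]
        assert offset.center_deg == pytest.approx(exact.center_deg, abs=1e-4)
        assert offset.fwhm_deg == pytest.approx(exact.fwhm_deg, rel=1e-3)


class TestCrystallinityIndex:
    def test_zero_background_is_hundred_percent(self):
        grid = np.linspace(10.0, 45.0, 701)
        d = waxs.Diffractogram1D(grid, np.exp(-0.5 * ((grid - 22.7) / 1.0) ** 2))
        bg = waxs.BackgroundFit("zero", grid[[0, -1]], np.zeros_like(grid), (10.0, 45.0), 0.0)
        assert waxs.crystallinity_index(d, bg) == pytest.approx(100.0, abs=1e-9)

    def test_background_equal_to_signal_is_zero_percent(self):
        grid = np.linspace(10.0, 45.0, 701)
        y = 5.0 + np.exp(-0.5 * ((grid - 20.0) / 6.0) ** 2)
        d = waxs.Diffractogram1D(grid, y)
        area = float(np.trapezoid(y, grid))
        bg = waxs.BackgroundFit("signal", grid[[0, -1]], y, (10.0, 45.0), area)
        assert waxs.crystallinity_index(d, bg) == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_uniform_rescaling(self):
        d = sd.gen_diffractogram(sd.pattern_with_fraction(0.25), seed=3)
        bg = waxs.fit_background(d)
        v1 = waxs.crystallinity_index(d, bg)
        d2 = waxs.Diffractogram1D(d.twotheta_deg, d.intensity * 7.5, d.wavelength_A)
        bg2 = waxs.fit_background(d2)
        v2 = waxs.crystallinity_index(d2, bg2)
        assert v2 == pytest.approx(v1, abs=0.3)

    @pytest.mark.parametrize("fraction", [0.1, 0.2, 0.25, 0.3])
    def test_recovers_generator_fraction(self, fraction):
        d = sd.gen_diffractogram(sd.pattern_with_fraction(fraction), seed=11)
        bg = waxs.fit_background(d)
        assert waxs.crystallinity_index(d, bg) == pytest.approx(100.0 * fraction, abs=3.0)


class TestFullAnalysis:
    def test_report_contains_all_reference_reflections(self):
        d = sd.gen_diffractogram(sd.pattern_with_fraction(0.4), seed=5)
        result = waxs.analyze_diffractogram(
            d, init_centers_deg={"(1-10)": 14.5, "(110)": 16.8, "(200)": 22.7, "(004)": 34.6}
        )
        assert set(result.lattice_spacings_A) == {"(1-10)", "(110)", "(200)", "(004)"}
        assert result.lattice_spacings_A["(200)"] == pytest.approx(3.91, abs=0.05)
        assert all(v > 0 for v in result.crystallite_sizes_nm.values())
        # internal consistency of the report
        expected_pct = 100.0 * (result.area_sample - result.area_background) / result.area_sample
        assert result.crystallinity_pct == pytest.approx(expected_pct, abs=1e-9)
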