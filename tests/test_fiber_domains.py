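"""Profile extraction, peak filtering and the dark/bright domain statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pellimetrics import fiber_domains as fd
from pellimetrics import synthetic_data as sd
from tests.oracles import brute_force_filtered_positions


def make_profile(y, step_nm=25.0):
    y = np.asarray(y, float)
    return fd.IntensityProfile(np.arange(len(y)) * step_nm, y, pixel_size_nm=step_nm)


def gaussian_bumps(n, bumps, step_nm=25.0):
    x = np.arange(n) * step_nm
    y = np.zeros(n)
    for center, height, sigma in bumps:
        y += height * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return make_profile(y, step_nm)


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        image = np.full((40, 60), 3.7)
        trace = np.array([[5.0, 20.0], [55.0, 20.0]])
        prof = fd.extract_profile(image, trace, pixel_size_nm=50.0, width_nm=500.0)
        assert np.allclose(prof.intensities, 3.7)

    def test_bright_stripe_peak_is_centered_at_crossing(self):
        image = np.zeros((40, 80))
        image[:, 38:43] = 10.0  # vertical stripe centered at x = 40
        trace = np.array([[5.0, 20.0], [75.0, 20.0]])
        prof = fd.extract_profile(image, trace, pixel_size_nm=50.0, width_nm=300.0)
        peak_pos = prof.positions_nm[np.argmax(prof.intensities)]
        assert peak_pos == pytest.approx((40.0 - 5.0) * 50.0, abs=100.0)

    def test_wider_averaging_reduces_noise_variance(self):
        rng = np.random.default_rng(0)
        image = rng.normal(100.0, 10.0, (60, 80))
        trace = np.array([[5.0, 30.0], [75.0, 30.0]])
        narrow = fd.extract_profile(image, trace, 50.0, width_nm=200.0)
        wide = fd.extract_profile(image, trace, 50.0, width_nm=800.0)
        assert wide.intensities.std() < narrow.intensities.std()

    def test_trace_leaving_image_rejected(self):
        image = np.zeros((20, 20))
        trace = np.array([[5.0, 10.0], [40.0, 10.0]])
        with pytest.raises(fd.TraceGeometryError):
            fd.extract_profile(image, trace, 50.0)


class TestFindPeaksFiltered:
    def test_flat_profile_has_no_peaks(self):
        peaks = fd.find_peaks_filtered(make_profile(np.full(64, 5.0)))
        assert peaks.peaks == ()

    def test_median_cut_drops_the_weak_of_two_peaks(self):
        # prominences 10 and 3: median 6.5, the 3-peak is strictly below
        prof = gaussian_bumps(200, [(1000.0, 10.0, 120.0), (3000.0, 3.0, 120.0)])
        peaks = fd.find_peaks_filtered(prof)
        assert len(peaks.peaks) == 1
        assert peaks.peaks[0].position_nm == pytest.approx(1000.0, abs=30.0)
        assert peaks.median_prominence == pytest.approx(6.5, rel=0.05)

    def test_equal_prominence_peaks_all_retained(self):
        # ties at the median are kept: identical peaks, odd count
        prof = gaussian_bumps(280, [(1000.0, 5.0, 100.0), (3000.0, 5.0, 100.0), (5000.0, 5.0, 100.0)])
        peaks = fd.find_peaks_filtered(prof)
        assert len(peaks.peaks) == 3

    def test_narrow_peaks_removed_by_fwhm_filter(self):
        prof = gaussian_bumps(200, [(1000.0, 10.0, 20.0), (3000.0, 10.0, 120.0)])
        peaks = fd.find_peaks_filtered(prof)
        assert [round(p.position_nm) for p in peaks.peaks] == [3000]

    def test_close_pair_keeps_higher_prominence(self):
        prof = gaussian_bumps(
            400, [(2000.0, 10.0, 60.0), (2075.0, 6.0, 60.0), (6000.0, 1.0, 80.0)], step_nm=25.0
        )
        peaks = fd.find_peaks_filtered(prof, min_fwhm_nm=50.0, min_spacing_nm=100.0)
        positions = [p.position_nm for p in peaks.peaks]
        assert not any(1950 < p < 2200 and abs(p - 2000) > 40 for p in positions)
        assert any(abs(p - 2000) <= 40 for p in positions)

    def test_matches_brute_force_enumerator_on_random_profiles(self):
        """Set-equality with the exhaustive enumerator on 200 random profiles
        of up to 64 samples."""
        step = 25.0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = rng.integers(16, 65)
            y = np.cumsum(rng.normal(size=n))
            y = np.convolve(y, np.ones(3) / 3.0, mode="same") + rng.normal(0, 0.05, n)
            prof = make_profile(y, step)
            got = sorted(
                int(round(p.position_nm / step)) for p in fd.find_peaks_filtered(prof).peaks
            )
            expected = brute_force_filtered_positions(y, step)
            assert got == expected, f"seed {seed}: {got} != {expected}"


class TestSegmentDomains:
    def test_crystallinity_arithmetic(self):
        seg = fd.DomainSegmentation(bright_lengths_nm=(200.0, 200.0), dark_lengths_nm=(600.0, 600.0))
        assert seg.crystallinity_pct == pytest.approx(75.0, abs=1e-12)

    def test_square_wave_profile_fifty_percent(self):
        # exact plateaus keep all prominences tied, so the ≥-median cut
        # retains every peak; many periods make the end-discard negligible
        # (n bright domains always bracket n−1 dark ones)
        step = 5.0
        x = np.arange(0, 50 * 800.0, step)
        y = 10.0 * (np.sin(2 * np.pi * x / 800.0) > 0)
        prof = make_profile(y, step)
        peaks = fd.find_peaks_filtered(prof)
        seg = fd.segment_domains(prof, peaks)
        assert len(seg.bright_lengths_nm) == 50
        assert seg.crystallinity_pct == pytest.approx(50.0, abs=1.0)

    def test_insufficient_peaks_is_an_error(self):
        prof = gaussian_bumps(200, [(2500.0, 10.0, 120.0)])
        peaks = fd.find_peaks_filtered(prof)
        with pytest.raises(fd.InsufficientPeaksError):
            fd.segment_domains(prof, peaks)

    def test_counts_differ_by_one(self):
        prof = gaussian_bumps(
            400, [(1000.0, 8.0, 100.0), (3500.0, 9.0, 100.0), (6000.0, 10.0, 100.0)]
        )
        peaks = fd.find_peaks_filtered(prof)
        seg = fd.segment_domains(prof, peaks)
        assert len(seg.bright_lengths_nm) - len(seg.dark_lengths_nm) == 1
        assert all(l > 0 for l in seg.bright_lengths_nm + seg.dark_lengths_nm)

    @given(
        dark=st.lists(st.floats(50.0, 2000.0), min_size=1, max_size=8),
        bright=st.lists(st.floats(50.0, 2000.0), min_size=1, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_crystallinity_bounds(self, dark, bright):
        seg = fd.DomainSegmentation(tuple(bright), tuple(dark))
        assert 0.0 <= seg.crystallinity_pct <= 100.0
        expected = 100.0 * sum(dark) / (sum(dark) + sum(bright))
        assert seg.crystallinity_pct == pytest.approx(expected, abs=1e-9)


class TestSummarizeFibers:
    def test_single_fiber_summary_equals_its_values(self):
        seg = fd.DomainSegmentation((200.0, 220.0), (600.0,))
        table = fd.summarize_fibers([seg])
        assert table.loc["bright_length_nm", "mean"] == pytest.approx(210.0)
        assert table.loc["crystallinity_pct", "mean"] == pytest.approx(seg.crystallinity_pct)
        assert table.loc["crystallinity_pct", "n"] == 1

    def test_two_fiber_mean_and_sd(self):
        a = fd.DomainSegmentation((300.0,), (700.0,))  # 70%
        b = fd.DomainSegmentation((200.0,), (800.0,))  # 80%
        table = fd.summarize_fibers([a, b])
        assert table.loc["crystallinity_pct", "mean"] == pytest.approx(75.0)
        assert table.loc["crystallinity_pct", "sd"] == pytest.approx(7.0710678, rel=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fd.summarize_fibers([])


class TestMonotoneRecovery:
    def test_estimated_crystallinity_increases_with_truth(self):
        """Spearman ρ > 0.9 between true and estimated crystallinity across
        20 crystalline-fraction levels (profile-level pipeline)."""
        import scipy.stats

        truths, estimates = [], []
        for k, cryst_nm in enumerate(np.linspace(250.0, 1600.0, 20)):
            truth = sd.fixed_fiber_truth(
                crystalline_nm=float(cryst_nm),
                amorphous_nm=300.0,
                n_pairs=10,
                frame_shape=(24, 250),
            )
            per_seed = []
            for rep in range(3):
                pos, prof_y = sd.gen_intensity_profile(
                    truth, step_nm=20.0, noise_sd=2.0, seed=1000 * k + rep
                )
                prof = fd.IntensityProfile(pos, prof_y, pixel_size_nm=100.0)
                peaks = fd.find_peaks_filtered(prof)
                per_seed.append(fd.segment_domains(prof, peaks).crystallinity_pct)
            truths.append(truth.true_crystallinity)
            estimates.append(np.mean(per_seed))
        rho = scipy.stats.spearmanr(truths, estimates).statistic
        assert rho > 0.9
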