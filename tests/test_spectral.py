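"""Normalization, ROI handling, power spectra and band fluctuation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from venofluct import (
    DegenerateNoiseError,
    EmptyBandError,
    FrequencyBand,
    RoiTimeSeries,
    RoiConflictError,
    extract_series,
    find_cardiac_center,
    normalize_frames,
    power_spectrum,
    select_vessel_roi,
    sfi,
    time_domain_sd,
)

TR = 0.25


def _series(values, tr=TR):
    return RoiTimeSeries(np.asarray(values, dtype=float), tr=tr)


def _sinusoid(amp, bin_index, n, tr=TR, phase=0.3):
    t = np.arange(n) * tr
    f = bin_index / (n * tr)
    return _series(5.0 + amp * np.sin(2 * np.pi * f * t + phase), tr)


def _corner_masks(shape, side=2):
    nr, nc = shape
    masks = []
    for rs, cs in [(0, 0), (0, nc - side), (nr - side, 0), (nr - side, nc - side)]:
        m = np.zeros(shape, dtype=bool)
        m[rs : rs + side, cs : cs + side] = True
        masks.append(m)
    return masks


class TestNormalizeFrames:
    def test_constant_noise_scaling(self):
        frames = np.full((6, 6, 4), 2.0)
        frames[3, 3, :] = 10.0
        masks = _corner_masks((6, 6))
        normalized, noise_mean = normalize_frames(frames, masks)
        assert noise_mean == 2.0
        assert np.all(normalized[3, 3, :] == 5.0)

    def test_zero_noise_is_degenerate(self):
        frames = np.zeros((6, 6, 4))
        frames[3, 3, :] = 10.0
        with pytest.raises(DegenerateNoiseError):
            normalize_frames(frames, _corner_masks((6, 6)))

    def test_seeded_noise_mean_recovers_unity(self, rng):
        frames = np.abs(rng.normal(3.0, 0.5, size=(10, 10, 20)))
        masks = _corner_masks((10, 10), side=3)
        union = np.zeros((10, 10), dtype=bool)
        for m in masks:
            union |= m
        mu = np.abs(frames[union]).mean()  # direct-averaging oracle
        normalized, noise_mean = normalize_frames(frames, masks)
        assert noise_mean == pytest.approx(mu, rel=1e-12)
        assert np.abs(normalized[union]).mean() == pytest.approx(1.0, rel=1e-12)

    def test_overlapping_rois_conflict(self):
        frames = np.ones((6, 6, 4))
        masks = _corner_masks((6, 6))
        with pytest.raises(RoiConflictError):
            normalize_frames(frames, masks, exclude_rois=[masks[0]])

    def test_pixel_count_enforced(self):
        frames = np.ones((6, 6, 4))
        with pytest.raises(ValueError, match="pixels"):
            normalize_frames(frames, _corner_masks((6, 6)), pixels_per_roi=100)


class TestExtractSeries:
    def test_transient_exclusion_length(self):
        frames = np.random.default_rng(0).normal(5, 1, size=(4, 4, 180))
        roi = np.zeros((4, 4), dtype=bool)
        roi[1, 1] = roi[1, 2] = True
        series = extract_series(frames, roi, TR, n_transient=8)
        assert series.n == 172
        assert series.n_excluded_transient == 8

    def test_no_transient_keeps_all(self):
        frames = np.ones((4, 4, 10))
        roi = np.ones((4, 4), dtype=bool)
        assert extract_series(frames, roi, TR, n_transient=0).n == 10

    def test_single_pixel_identity(self):
        frames = np.zeros((3, 3, 12))
        ramp = np.arange(12, dtype=float)
        frames[2, 1, :] = ramp
        roi = np.zeros((3, 3), dtype=bool)
        roi[2, 1] = True
        series = extract_series(frames, roi, TR, n_transient=0)
        np.testing.assert_array_equal(series.values, ramp)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_series(np.ones((3, 3, 5)), np.zeros((3, 3), dtype=bool), TR, 0)


class TestSelectVesselRoi:
    def test_selects_seeded_bright_pixels(self, rng):
        img = rng.uniform(0, 1, size=(32, 32))
        bright = [(r, c) for r in (5, 6, 7) for c in (10, 11, 12)] + [(9, 9), (20, 20)]
        for r, c in bright:
            img[r, c] = 10 + rng.uniform()
        mask = np.ones((32, 32), dtype=bool)
        roi = select_vessel_roi(img, mask, n_pixels=11)
        assert roi.sum() == 11
        # brute-force oracle: the 11 largest values
        expect = set(
            map(tuple, np.argwhere(img >= np.sort(img.ravel())[-11]))
        )
        assert set(map(tuple, np.argwhere(roi))) == expect

    def test_mask_size_equals_request(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        roi = select_vessel_roi(img, mask, n_pixels=4)
        np.testing.assert_array_equal(roi, mask)

    def test_row_major_tie_break(self):
        img = np.ones((4, 4))
        roi = select_vessel_roi(img, np.ones((4, 4), dtype=bool), n_pixels=3)
        assert [tuple(x) for x in np.argwhere(roi)] == [(0, 0), (0, 1), (0, 2)]

    def test_too_small_mask_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            select_vessel_roi(np.ones((4, 4)), np.zeros((4, 4), dtype=bool), 11)


class TestTimeDomainSd:
    def test_constant_is_zero(self):
        assert time_domain_sd(_series([3.0] * 8)) == 0.0

    def test_alternating_unit(self):
        assert time_domain_sd(_series([1, -1, 1, -1])) == 1.0

    def test_population_normalization_vs_loop_oracle(self, rng):
        x = rng.normal(size=37)
        acc = sum((v - x.mean()) ** 2 for v in x) / x.size
        assert time_domain_sd(_series(x)) == pytest.approx(np.sqrt(acc), rel=1e-12)


class TestPowerSpectrum:
    def test_constant_series_all_zero(self):
        spec = power_spectrum(_series([4.0] * 16))
        assert np.allclose(spec.power, 0.0, atol=1e-20)

    def test_on_bin_sinusoid_power(self):
        n = 64
        spec = power_spectrum(_sinusoid(1.0, 5, n))
        # analytic DFT of a unit sinusoid: N^2/4 at the bin and its mirror
        assert spec.power[5] == pytest.approx(n**2 / 4, rel=1e-9)
        assert spec.power[n - 5] == pytest.approx(n**2 / 4, rel=1e-9)
        others = np.delete(spec.power, [5, n - 5])
        assert np.all(others < 1e-18 * n**2)

    def test_matches_direct_dft_loop(self, rng):
        x = rng.normal(size=12)
        spec = power_spectrum(_series(x))
        xc = x - x.mean()
        for m in range(12):
            X = sum(xc[k] * np.exp(-2j * np.pi * m * k / 12) for k in range(12))
            assert spec.power[m] == pytest.approx(abs(X) ** 2, abs=1e-9)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(16, 200))
    def test_parseval_identity(self, seed, n):
        x = np.random.default_rng(seed).normal(size=n)
        series = _series(x)
        spec = power_spectrum(series)
        sd_spectral = np.sqrt(spec.power.sum() / n**2)
        assert sd_spectral == pytest.approx(time_domain_sd(series), rel=1e-9)


class TestSfi:
    def test_constant_series_zero(self):
        spec = power_spectrum(_series([2.0] * 32))
        assert sfi(spec, FrequencyBand(0.0, 2.0)) == 0.0

    def test_on_bin_sinusoid_closed_form(self):
        amp = 0.37
        spec = power_spectrum(_sinusoid(amp, 7, 128))
        band = FrequencyBand(0.15, 0.3)  # bin 7 of 128 at TR 0.25 -> 0.21875 Hz
        assert sfi(spec, band) == pytest.approx(amp / np.sqrt(2), rel=1e-9)

    @pytest.mark.parametrize("n", [171, 172])  # odd and even: Nyquist handling
    def test_full_band_equals_time_domain_sd(self, n, rng):
        series = _series(rng.normal(size=n))
        spec = power_spectrum(series)
        full = FrequencyBand(0.0, spec.nyquist)
        assert sfi(spec, full) == pytest.approx(time_domain_sd(series), rel=1e-9)

    def test_band_additivity_in_quadrature(self, rng):
        series = _series(rng.normal(size=100))
        spec = power_spectrum(series)
        lo, hi = FrequencyBand(0.0, 0.9999), FrequencyBand(1.0, 2.0)
        union = FrequencyBand(0.0, 2.0)
        combined = np.hypot(sfi(spec, lo), sfi(spec, hi))
        assert combined == pytest.approx(sfi(spec, union), rel=1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(st.floats(0.01, 100.0), st.integers(0, 2**31 - 1))
    def test_scaling_equivariance(self, c, seed):
        x = np.random.default_rng(seed).normal(size=64)
        band = FrequencyBand(0.2, 0.5)
        base = sfi(power_spectrum(_series(x)), band)
        scaled = sfi(power_spectrum(_series(c * x)), band)
        assert scaled == pytest.approx(c * base, rel=1e-9)
        assert time_domain_sd(_series(c * x)) == pytest.approx(
            c * time_domain_sd(_series(x)), rel=1e-9
        )

    def test_empty_band_rejected(self):
        spec = power_spectrum(_series(np.arange(16.0)))
        with pytest.raises(EmptyBandError):
            sfi(spec, FrequencyBand(0.001, 0.01))  # below the first bin


class TestFindCardiacCenter:
    def test_finds_cardiac_peak(self):
        # bin 29 of N=100 at TR 0.25 is exactly 1.16 Hz
        spec = power_spectrum(_sinusoid(1.0, 29, 100))
        assert find_cardiac_center(spec) == pytest.approx(1.16, rel=1e-12)

    def test_single_peak_at_one_hz(self):
        spec = power_spectrum(_sinusoid(1.0, 25, 100))  # 1.0 Hz
        assert find_cardiac_center(spec) == pytest.approx(1.0, rel=1e-12)

    def test_equal_peaks_tie_to_lowest(self):
        from venofluct import BandSpectrum

        power = np.zeros(80)
        power[18] = power[80 - 18] = 5.0  # 0.9 Hz at df = 0.05
        power[22] = power[80 - 22] = 5.0  # 1.1 Hz
        spec = BandSpectrum(power, freq_resolution=0.05, nyquist=2.0, n_samples=80)
        assert find_cardiac_center(spec) == pytest.approx(0.9, rel=1e-12)

    def test_empty_window_rejected(self):
        spec = power_spectrum(_series(np.arange(16.0)))
        with pytest.raises(EmptyBandError):
            find_cardiac_center(spec, 0.01, 0.02)
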