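"""Synthetic acquisition generator: determinism, closed forms, round trips."""

import numpy as np
import pytest
from dataclasses import replace

from venofluct import (
    LOW_BAND,
    RESPIRATORY_BAND,
    FrequencyBand,
    RoiConflictError,
    cardiac_band,
    extract_series,
    normalize_frames,
    power_spectrum,
    sfi,
)
from venofluct.synth import (
    SimulationScenario,
    default_geometry,
    end_to_end_recovery,
    simulate_image_stack,
    simulate_roi_series,
)


class TestScenario:
    def test_default_sampling_layout(self):
        scen = SimulationScenario()
        assert scen.n_frames == 180
        assert scen.n_analysis == 172

    def test_super_nyquist_frequency_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SimulationScenario(delta_y_by_band={"cardiac": (0.02, 2.5)})

    def test_non_increasing_thicknesses_rejected(self):
        with pytest.raises(ValueError):
            SimulationScenario(thicknesses=(9.0, 7.0))

    def test_frequency_snapping_is_on_grid(self):
        scen = SimulationScenario()
        f = scen.snap_frequency(0.30)
        df = 1.0 / (scen.n_analysis * scen.tr)
        assert f == pytest.approx(round(f / df) * df)
        assert abs(f - 0.30) < df


class TestSimulateRoiSeries:
    def test_seed_determinism_bit_identical(self):
        a, _ = simulate_roi_series(SimulationScenario(seed=42), 11.0)
        b, _ = simulate_roi_series(SimulationScenario(seed=42), 11.0)
        np.testing.assert_array_equal(a.values, b.values)
        c, _ = simulate_roi_series(SimulationScenario(seed=43), 11.0)
        assert not np.array_equal(a.values, c.values)

    def test_truth_record_conserves_scenario(self, quiet_scenario):
        _, truth = simulate_roi_series(quiet_scenario, 9.0)
        assert truth.delta_y_by_band == {
            k: v[0] for k, v in quiet_scenario.delta_y_by_band.items()
        }
        assert truth.velocity_sfi == quiet_scenario.velocity_sfi
        assert truth.mean_signal == pytest.approx(
            quiet_scenario.signal_per_mm * truth.refocused_thickness_mm
        )

    def test_silent_scenario_is_constant(self):
        scen = SimulationScenario(
            delta_y_by_band={}, velocity_sfi=0.0, noise_sd=0.0, seed=1
        )
        series, truth = simulate_roi_series(scen, 11.0)
        np.testing.assert_allclose(series.values, truth.mean_signal)

    def test_single_band_sfi_closed_form(self):
        # SFI/SI of a pure respiratory modulation equals 2*C1*(1-Y)*TE*ΔY
        dy = 0.012
        scen = SimulationScenario(
            delta_y_by_band={"respiratory": (dy, 0.30)},
            velocity_sfi=0.0,
            noise_sd=0.0,
            seed=3,
        )
        series, truth = simulate_roi_series(scen, 11.0)
        ratio = sfi(power_spectrum(series), RESPIRATORY_BAND) / series.mean
        assert ratio == pytest.approx(scen.blood_model.sensitivity * dy, rel=1e-9)

    def test_zero_velocity_sfi_proportional_to_si(self):
        scen = SimulationScenario(
            thicknesses=(7.0, 15.0), velocity_sfi=0.0, noise_sd=0.0, seed=4
        )
        out = {}
        for th in (7.0, 15.0):
            series, truth = simulate_roi_series(scen, th)
            out[th] = (sfi(power_spectrum(series), RESPIRATORY_BAND), truth.mean_signal)
        assert out[15.0][0] / out[7.0][0] == pytest.approx(
            out[15.0][1] / out[7.0][1], rel=1e-9
        )

    def test_unused_band_holds_only_noise_floor(self):
        scen = SimulationScenario(
            delta_y_by_band={"respiratory": (0.012, 0.30)},
            velocity_sfi=0.0,
            noise_sd=0.0,
            seed=5,
        )
        series, _ = simulate_roi_series(scen, 11.0)
        assert sfi(power_spectrum(series), LOW_BAND) <= 1e-10 * series.mean

    def test_nonlinear_mode_close_to_linearized(self):
        lin = SimulationScenario(noise_sd=0.0, seed=6)
        non = replace(lin, nonlinear=True)
        a, _ = simulate_roi_series(lin, 11.0)
        b, _ = simulate_roi_series(non, 11.0)
        # total modulation depth is ~9% peak, so second-order relaxation
        # terms stay below ~1% of the signal
        np.testing.assert_allclose(b.values, a.values, rtol=1e-2)
        assert np.abs(b.values / a.values - 1).max() > 1e-4  # genuinely different paths


class TestSimulateImageStack:
    def test_vessel_roundtrip_reproduces_series(self, quiet_scenario):
        stack, geom, _ = simulate_image_stack(quiet_scenario, 9.0)
        series, _ = simulate_roi_series(quiet_scenario, 9.0)
        extracted = extract_series(
            stack, geom.vessel_mask, quiet_scenario.tr, quiet_scenario.n_transient
        )
        np.testing.assert_allclose(extracted.values, series.values, rtol=1e-12)

    def test_background_normalizes_to_unity(self, rng):
        scen = SimulationScenario(seed=7)
        geom = default_geometry(background_noise_mean=3.5, receiver_gain=2.0)
        stack, geom, _ = simulate_image_stack(scen, 11.0, geom)
        union = np.zeros(geom.shape, dtype=bool)
        for m in geom.noise_masks:
            union |= m
        mu = np.abs(stack[union]).mean()  # direct-average oracle
        normalized, noise_mean = normalize_frames(stack, geom.noise_masks)
        assert noise_mean == pytest.approx(mu, rel=1e-12)
        assert np.abs(normalized[union]).mean() == pytest.approx(1.0, rel=1e-12)
        # empirical mean of |N(0, σ)| background tracks the configured level ×gain
        assert noise_mean == pytest.approx(3.5 * 2.0, rel=0.05)

    def test_overlapping_geometry_rejected(self, quiet_scenario):
        geom = default_geometry()
        bad = replace(geom, skull_mask=geom.vessel_mask.copy())
        with pytest.raises(RoiConflictError):
            simulate_image_stack(quiet_scenario, 9.0, bad)


class TestEndToEndRecovery:
    def test_zero_noise_recovery_is_exact(self, quiet_scenario):
        rec = end_to_end_recovery(quiet_scenario)
        for band, injected in rec.injected_delta_y.items():
            assert rec.recovered_delta_y[band] == pytest.approx(injected, rel=1e-9)
        assert rec.recovered_intercepts["cardiac"] == pytest.approx(
            quiet_scenario.velocity_sfi, abs=1e-9
        )
        assert rec.recovered_intercepts["respiratory"] == pytest.approx(0.0, abs=1e-9)

    def test_cardiac_band_follows_detected_peak(self, quiet_scenario):
        rec = end_to_end_recovery(quiet_scenario)
        f_card = quiet_scenario.snap_frequency(1.16)
        assert all(c == pytest.approx(f_card, rel=1e-12) for c in rec.cardiac_centers)

    def test_moderate_noise_recovery_accuracy(self):
        # at the default noise level (~0.6% of SI) the per-band amplitudes
        # come back to within a few percent in a typical experiment
        errs = []
        for seed in range(20):
            rec = end_to_end_recovery(SimulationScenario(seed=seed))
            errs.extend(
                abs(rec.recovered_delta_y[b] - rec.injected_delta_y[b])
                / rec.injected_delta_y[b]
                for b in rec.injected_delta_y
            )
        assert np.median(errs) <= 0.10

    def test_zero_velocity_intercept_ci_covers_zero(self):
        hits = total = 0
        for seed in range(60):
            scen = SimulationScenario(velocity_sfi=0.0, seed=seed)
            rec = end_to_end_recovery(scen)
            lo, hi = rec.recovered_intercept_ci["cardiac"]
            hits += lo <= 0.0 <= hi
            total += 1
        assert hits / total >= 0.90

    def test_too_few_thicknesses_rejected(self):
        scen = SimulationScenario(thicknesses=(9.0, 11.0))
        with pytest.raises(ValueError, match="3 thicknesses"):
            end_to_end_recovery(scen)
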