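"""Synthetic multi-thickness SE-EPI acquisitions with known ground truth.

The generator embodies the forward model the analysis inverts: the mean
vessel signal SI is proportional to the refocused slab (slice thickness
minus the blood displacement over TE/2), oxygenation fluctuation modulates
the signal *relatively* (a per-band sinusoid of relative SD
``2*C1*(1-Y)*TE*ΔY_band``), the velocity fluctuation adds an *absolute*,
thickness-independent sinusoid, and white Gaussian noise sits on top::

    S(t) = SI * (1 + Σ_b √2·a_b·sin(2π f_b t + φ_b))
           + √2·velocity_sfi·sin(2π f_v t + ψ) + ε(t),
    a_b = 2*C1*(1-Y)*TE*ΔY_b

ΔY and velocity_sfi are SD-type amplitudes, hence the √2 on each sinusoid;
with on-bin frequencies the band SFI of a noiseless series is exactly
``a_b*SI + velocity_sfi·[band contains f_v]``, so the slice-thickness
separation recovers the injected values in closed form.  Frequencies are
snapped to the DFT grid of the retained (post-transient) samples by
default; a ``nonlinear=True`` switch re-exponentiates the relaxation model
per time point instead of using the linearized modulation.

All randomness (phases, noise) derives from ``scenario.seed`` and the slice
thickness, so identical scenarios are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .blood_model import BloodModel, FlowGeometry, r2_rate, refocused_thickness
from .errors import RoiConflictError
from .separation import AcquisitionPoint, SeparationResult, delta_y_percent, separate
from .spectral import (
    LOW_BAND,
    RESPIRATORY_BAND,
    FrequencyBand,
    RoiTimeSeries,
    cardiac_band,
    find_cardiac_center,
    noise_floor_per_bin,
    power_spectrum,
    sfi,
)

__all__ = [
    "SimulationScenario",
    "SimulationTruth",
    "StackGeometry",
    "RecoveryReport",
    "default_geometry",
    "simulate_roi_series",
    "simulate_image_stack",
    "end_to_end_recovery",
]

ROOT_TWO = math.sqrt(2.0)


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic multi-thickness experiment.

    Defaults mirror the resting-state sinus protocol: five slice
    thicknesses 7–15 mm, TR 250 ms, 45 s per acquisition (180 frames, the
    first 8 transient), TE 30 ms, per-band oxygenation amplitudes
    (1.8%, 1.2%, 2.4%) at (0.06, 0.30, 1.16) Hz, mean sinus velocity
    97.2 mm/s, and a velocity-fluctuation amplitude of 0.35 SFI units at
    the cardiac frequency.
    """

    thicknesses: tuple[float, ...] = (7.0, 9.0, 11.0, 13.0, 15.0)
    tr: float = 0.25
    duration: float = 45.0
    te: float = 0.030
    blood_model: BloodModel = field(default_factory=BloodModel)
    delta_y_by_band: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "low": (0.018, 0.06),
            "respiratory": (0.012, 0.30),
            "cardiac": (0.024, 1.16),
        }
    )
    velocity_sfi: float = 0.35
    velocity_frequency: float | None = None  # None → the cardiac band frequency
    velocity_phase_locked: bool = True
    mean_velocity_mm_s: float = 97.2
    signal_per_mm: float = 2.5
    noise_sd: float = 0.15
    noise_sd_fraction_of_si: float | None = None  # overrides noise_sd when set
    motion_amplitude: float = 0.0  # pixels, in-plane, respiratory frequency
    n_transient: int = 8
    on_bin: bool = True
    nonlinear: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.thicknesses) < 1 or any(
            b <= a for a, b in zip(self.thicknesses, self.thicknesses[1:])
        ):
            raise ValueError("thicknesses must be strictly increasing")
        if self.tr <= 0 or self.duration <= 0 or self.te <= 0:
            raise ValueError("tr, duration, te must be positive")
        nyq = 1.0 / (2.0 * self.tr)
        for label, (amp, freq) in self.delta_y_by_band.items():
            if amp < 0:
                raise ValueError(f"band {label!r}: amplitude must be >= 0")
            if freq >= nyq:
                raise ValueError(f"band {label!r}: {freq} Hz >= Nyquist {nyq} Hz")
        if self.velocity_frequency is not None and self.velocity_frequency >= nyq:
            raise ValueError("velocity frequency >= Nyquist")
        if self.velocity_sfi < 0 or self.noise_sd < 0 or self.motion_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.n_transient < 0 or self.n_transient >= self.n_frames:
            raise ValueError("n_transient out of range")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.tr))

    @property
    def n_analysis(self) -> int:
        return self.n_frames - self.n_transient

    def snap_frequency(self, freq: float) -> float:
        """Nearest nonzero DFT-bin frequency of the retained segment."""
        if not self.on_bin:
            return freq
        df = 1.0 / (self.n_analysis * self.tr)
        return max(1, int(round(freq / df))) * df

    def rng_for(self, thickness: float) -> np.random.Generator:
        return np.random.default_rng([self.seed, int(round(thickness * 1000))])


@dataclass
class SimulationTruth:
    """Ground-truth record returned with every simulated acquisition."""

    slice_thickness: float
    mean_signal: float
    refocused_thickness_mm: float
    delta_y_by_band: dict[str, float]
    frequencies_by_band: dict[str, float]  # after any bin snapping
    relative_amplitudes: dict[str, float]  # a_b = 2*C1*(1-Y)*TE*ΔY_b
    velocity_sfi: float
    velocity_frequency: float
    noise_sd: float
    motion_amplitude: float = 0.0


def _timecourse(
    scenario: SimulationScenario, thickness: float, rng: np.random.Generator
) -> tuple[np.ndarray, SimulationTruth]:
    """Full-length (transient included) vessel signal and its truth record."""
    if thickness not in scenario.thicknesses:
        raise ValueError(f"thickness {thickness} not in scenario")
    model = scenario.blood_model
    geom = FlowGeometry(
        slice_thickness=thickness, velocity=scenario.mean_velocity_mm_s, te=scenario.te
    )
    slab = refocused_thickness(geom)
    si = scenario.signal_per_mm * slab

    n = scenario.n_frames
    # time origin at the first retained frame so on-bin sinusoids are exactly
    # periodic over the analyzed segment
    t = (np.arange(n) - scenario.n_transient) * scenario.tr

    freqs: dict[str, float] = {}
    amps: dict[str, float] = {}
    dys: dict[str, float] = {}
    phases: dict[str, float] = {}
    signal = np.zeros(n)
    delta_y_t = np.zeros(n)
    for label, (dy, freq) in scenario.delta_y_by_band.items():
        f = scenario.snap_frequency(freq)
        phi = float(rng.uniform(0.0, 2.0 * math.pi))
        freqs[label], dys[label], phases[label] = f, dy, phi
        amps[label] = model.sensitivity * dy
        if scenario.nonlinear:
            delta_y_t += ROOT_TWO * dy * np.sin(2.0 * math.pi * f * t + phi)
        else:
            signal += ROOT_TWO * amps[label] * np.sin(2.0 * math.pi * f * t + phi)
    if scenario.nonlinear:
        y0 = model.y_baseline
        r2_0 = r2_rate(model, y0)
        y_t = np.clip(y0 + delta_y_t, 0.0, 1.0)
        r2_t = model.c1 * (1.0 - y_t) ** 2 + model.c2
        values = si * np.exp(-(r2_t - r2_0) * model.te)
    else:
        values = si * (1.0 + signal)

    fv = scenario.velocity_frequency
    if fv is None:
        fv = scenario.delta_y_by_band.get("cardiac", (0.0, 1.16))[1]
    fv = scenario.snap_frequency(fv)
    if scenario.velocity_phase_locked and "cardiac" in phases and fv == freqs.get("cardiac"):
        psi = phases["cardiac"]
    else:
        psi = float(rng.uniform(0.0, 2.0 * math.pi))
    if scenario.velocity_sfi > 0:
        values = values + ROOT_TWO * scenario.velocity_sfi * np.sin(
            2.0 * math.pi * fv * t + psi
        )
    sigma = (
        scenario.noise_sd_fraction_of_si * si
        if scenario.noise_sd_fraction_of_si is not None
        else scenario.noise_sd
    )
    if sigma > 0:
        values = values + rng.normal(0.0, sigma, size=n)

    truth = SimulationTruth(
        slice_thickness=thickness,
        mean_signal=si,
        refocused_thickness_mm=slab,
        delta_y_by_band=dys,
        frequencies_by_band=freqs,
        relative_amplitudes=amps,
        velocity_sfi=scenario.velocity_sfi,
        velocity_frequency=fv,
        noise_sd=sigma,
        motion_amplitude=scenario.motion_amplitude,
    )
    return values, truth


def simulate_roi_series(
    scenario: SimulationScenario, thickness: float
) -> tuple[RoiTimeSeries, SimulationTruth]:
    """Analysis-ready vessel ROI series (transient frames already dropped)."""
    rng = scenario.rng_for(thickness)
    values, truth = _timecourse(scenario, thickness, rng)
    series = RoiTimeSeries(
        values[scenario.n_transient :],
        tr=scenario.tr,
        n_excluded_transient=scenario.n_transient,
        roi_id=f"vessel_st{thickness:g}",
    )
    return series, truth


@dataclass
class StackGeometry:
    """Pixel layout of a synthetic slice: vessel, skull edge, corner noise ROIs."""

    shape: tuple[int, int]
    vessel_mask: np.ndarray
    skull_mask: np.ndarray
    noise_masks: list[np.ndarray]
    background_noise_mean: float = 1.0
    skull_high: float = 20.0
    skull_low: float = 4.0
    receiver_gain: float = 1.0

    def all_masks(self) -> list[np.ndarray]:
        return [self.vessel_mask, self.skull_mask, *self.noise_masks]


def default_geometry(
    shape: tuple[int, int] = (48, 48),
    noise_side: int = 6,
    n_vessel: int = 11,
    background_noise_mean: float = 1.0,
    receiver_gain: float = 1.0,
) -> StackGeometry:
    """Small slice layout: central vessel blob, skull edge above it, 4 corner ROIs."""
    nr, nc = shape
    vessel = np.zeros(shape, dtype=bool)
    r0, c0 = nr // 2, nc // 2
    coords = [(r0 + dr, c0 + dc) for dr in range(3) for dc in range(4)]
    for r, c in coords[:n_vessel]:
        vessel[r, c] = True
    skull = np.zeros(shape, dtype=bool)
    skull[nr // 4 : nr // 4 + 4, c0 : c0 + 4] = True
    noise_masks = []
    s = noise_side
    for rs, cs in [(1, 1), (1, nc - s - 1), (nr - s - 1, 1), (nr - s - 1, nc - s - 1)]:
        m = np.zeros(shape, dtype=bool)
        m[rs : rs + s, cs : cs + s] = True
        noise_masks.append(m)
    return StackGeometry(
        shape=shape,
        vessel_mask=vessel,
        skull_mask=skull,
        noise_masks=noise_masks,
        background_noise_mean=background_noise_mean,
        receiver_gain=receiver_gain,
    )


def simulate_image_stack(
    scenario: SimulationScenario,
    thickness: float,
    geometry: StackGeometry | None = None,
) -> tuple[np.ndarray, StackGeometry, SimulationTruth]:
    """Full-frame synthetic stack: vessel series, static skull edge, noise floor.

    Every vessel pixel carries the ROI-mean signal, so extracting the vessel
    ROI reproduces :func:`simulate_roi_series` exactly (zero motion).  The
    skull block holds a static high-contrast stripe pattern; background
    pixels carry magnitude noise of known mean (0 when the scenario is
    noiseless); optional rigid in-plane motion is applied as a sinusoidal
    x-shift at the respiratory frequency via linear interpolation.
    """
    geometry = geometry if geometry is not None else default_geometry()
    nr, nc = geometry.shape
    union = np.zeros(geometry.shape, dtype=bool)
    for i, m in enumerate(geometry.all_masks()):
        m = np.asarray(m).astype(bool)
        if m.shape != geometry.shape:
            raise ValueError(f"mask {i} shape mismatch")
        if np.any(union & m):
            raise RoiConflictError("geometry masks overlap")
        union |= m

    rng = scenario.rng_for(thickness)
    values, truth = _timecourse(scenario, thickness, rng)
    n = values.size

    stack = np.zeros((nr, nc, n))
    if geometry.background_noise_mean > 0:
        sigma_bg = geometry.background_noise_mean * math.sqrt(math.pi / 2.0)
        background = np.abs(rng.normal(0.0, sigma_bg, size=(nr, nc, n)))
        stack[~geometry.vessel_mask & ~geometry.skull_mask] = background[
            ~geometry.vessel_mask & ~geometry.skull_mask
        ]
    # static skull edge: a high-contrast ramp across columns -> strong,
    # spatially coherent x-gradient (an alternating pattern would cancel in
    # the ROI-mean gradient vector)
    skull_rows, skull_cols = np.nonzero(geometry.skull_mask)
    c_lo, c_hi = skull_cols.min(), skull_cols.max()
    frac = (skull_cols - c_lo) / max(c_hi - c_lo, 1)
    skull_vals = geometry.skull_low + frac * (geometry.skull_high - geometry.skull_low)
    stack[skull_rows, skull_cols, :] = skull_vals[:, None]
    stack[geometry.vessel_mask] = values[None, :]

    if scenario.motion_amplitude > 0:
        f_resp = scenario.snap_frequency(
            scenario.delta_y_by_band.get("respiratory", (0.0, 0.30))[1]
        )
        phi_m = float(rng.uniform(0.0, 2.0 * math.pi))
        t = (np.arange(n) - scenario.n_transient) * scenario.tr
        shifts = scenario.motion_amplitude * np.sin(2.0 * math.pi * f_resp * t + phi_m)
        for j in range(n):
            stack[:, :, j] = ndimage.shift(
                stack[:, :, j], (0.0, shifts[j]), order=1, mode="nearest"
            )
    return stack * geometry.receiver_gain, geometry, truth


@dataclass
class RecoveryReport:
    """Injected versus recovered quantities of one synthetic experiment."""

    injected_delta_y: dict[str, float]
    recovered_delta_y: dict[str, float]
    recovered_delta_y_ci: dict[str, tuple[float, float]]
    injected_velocity_sfi: float
    recovered_intercepts: dict[str, float]
    recovered_intercept_ci: dict[str, tuple[float, float]]
    separations: dict[str, SeparationResult]
    points: list[AcquisitionPoint]
    cardiac_centers: list[float]


def end_to_end_recovery(
    scenario: SimulationScenario,
    noise_floor_correction: bool | None = None,
) -> RecoveryReport:
    """Run spectral → separation → ΔY on all thicknesses of a scenario.

    ``noise_floor_correction`` subtracts the white-noise per-bin power
    (estimated from out-of-band bins) from each band power before taking
    the SFI; by default it is applied whenever the scenario has noise.
    """
    if len(scenario.thicknesses) < 3:
        raise ValueError("need >= 3 thicknesses for the separation regression")
    if noise_floor_correction is None:
        noise_floor_correction = (
            scenario.noise_sd > 0 or bool(scenario.noise_sd_fraction_of_si)
        )

    points: list[AcquisitionPoint] = []
    centers: list[float] = []
    injected: dict[str, float] = {}
    for th in scenario.thicknesses:
        series, truth = simulate_roi_series(scenario, th)
        injected = truth.delta_y_by_band
        spectrum = power_spectrum(series)
        center = find_cardiac_center(spectrum)
        centers.append(center)
        bands = {"low": LOW_BAND, "respiratory": RESPIRATORY_BAND, "cardiac": cardiac_band(center)}
        floor = (
            noise_floor_per_bin(spectrum, list(bands.values()))
            if noise_floor_correction
            else 0.0
        )
        sfis = {label: sfi(spectrum, band, noise_power_per_bin=floor) for label, band in bands.items()}
        points.append(
            AcquisitionPoint(
                slice_thickness=th,
                mean_signal=series.mean,
                sfi_by_band=sfis,
                location_id="synthetic",
            )
        )

    model = scenario.blood_model
    separations: dict[str, SeparationResult] = {}
    rec_dy: dict[str, float] = {}
    rec_dy_ci: dict[str, tuple[float, float]] = {}
    icpts: dict[str, float] = {}
    icpt_ci: dict[str, tuple[float, float]] = {}
    for label in injected:
        res = separate(points, label)
        separations[label] = res
        slope = max(res.slope, 0.0)
        dy_pct, ci_pct = delta_y_percent(replace(res, slope=slope), model)
        rec_dy[label] = dy_pct / 100.0
        rec_dy_ci[label] = (ci_pct[0] / 100.0, ci_pct[1] / 100.0)
        icpts[label] = res.intercept
        icpt_ci[label] = res.intercept_ci95

    return RecoveryReport(
        injected_delta_y=dict(injected),
        recovered_delta_y=rec_dy,
        recovered_delta_y_ci=rec_dy_ci,
        injected_velocity_sfi=scenario.velocity_sfi,
        recovered_intercepts=icpts,
        recovered_intercept_ci=icpt_ci,
        separations=separations,
        points=points,
        cardiac_centers=centers,
    )
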