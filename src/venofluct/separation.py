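"""Slice-thickness separation of oxygenation- and flow-driven fluctuation.

The SE blood signal grows in proportion to slice thickness (more refocused
blood), and so does the fluctuation caused by blood oxygenation — it is a
fixed *relative* modulation ΔS/S.  The fluctuation caused by blood-velocity
variation is independent of thickness once the slice covers the whole
velocity-variation slab.  Regressing band-limited SFI on mean signal
intensity across slice thicknesses therefore separates the two: the slope
is ΔS/S (convertible to ΔY), the y-intercept is the velocity component.

The regression is ordinary least squares with t-based 95% confidence
intervals; points from all retained locations and subjects are pooled into
one regression per band.

Validity screening per slice location: the mean signal must be linear in
slice thickness (R² above threshold, default 0.77 — evidence of constant
vessel geometry), and the along-vessel velocity derivative must be small
(|d| <= 0.1, same evidence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .blood_model import BloodModel, delta_y_from_slope

__all__ = [
    "AcquisitionPoint",
    "SeparationResult",
    "ScreeningDecision",
    "linearity_r2",
    "screen_location",
    "separate",
    "delta_y_percent",
]

R2_THRESHOLD = 0.77
DERIV_THRESHOLD = 0.1


@dataclass
class AcquisitionPoint:
    """One slice thickness's (mean signal, per-band SFI) measurement."""

    slice_thickness: float
    mean_signal: float
    sfi_by_band: dict[str, float] = field(default_factory=dict)
    location_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if self.mean_signal <= 0:
            raise ValueError("mean_signal must be positive")
        if any(v < 0 for v in self.sfi_by_band.values()):
            raise ValueError("SFI values must be non-negative")


@dataclass
class SeparationResult:
    """OLS fit of band SFI on mean signal intensity.

    ``slope`` is the dimensionless ΔS/S gradient; ``intercept`` (SFI units)
    is the thickness-independent velocity-fluctuation component.
    """

    band: str
    slope: float
    intercept: float
    r: float
    p: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    n_points: int


@dataclass
class ScreeningDecision:
    include: bool
    reason: str


def linearity_r2(thicknesses, mean_signals) -> float:
    """Coefficient of determination of mean signal regressed on thickness.

    High R² indicates the mean signal grows linearly with slice thickness,
    i.e. the vessel cross-section is constant over the slab.
    """
    x = np.asarray(thicknesses, dtype=float)
    y = np.asarray(mean_signals, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 (thickness, mean signal) pairs")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct thicknesses")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)


def screen_location(
    r2: float,
    velocity_derivative: float,
    r2_threshold: float = R2_THRESHOLD,
    deriv_threshold: float = DERIV_THRESHOLD,
) -> ScreeningDecision:
    """Include a slice location iff R² > threshold and |velocity derivative| <= threshold."""
    reasons = []
    if not r2 > r2_threshold:
        reasons.append(f"linearity: R²={r2:.3g} <= {r2_threshold}")
    if not abs(velocity_derivative) <= deriv_threshold:
        reasons.append(
            f"velocity-derivative: |{velocity_derivative:.3g}| > {deriv_threshold}"
        )
    if reasons:
        return ScreeningDecision(False, "; ".join(reasons))
    return ScreeningDecision(True, "passed")


def separate(points: list[AcquisitionPoint], band: str) -> SeparationResult:
    """Pooled OLS of band SFI on mean signal across acquisitions.

    Returns slope, intercept, Pearson r, two-sided p, and t-based 95%
    confidence intervals for slope and intercept.  A negative fitted slope
    is reported as-is with a warning (it has no ΔY interpretation).
    """
    if len(points) < 3:
        raise ValueError("need >= 3 acquisition points")
    x = np.array([p.mean_signal for p in points], dtype=float)
    try:
        y = np.array([p.sfi_by_band[band] for p in points], dtype=float)
    except KeyError as exc:
        raise KeyError(f"band {band!r} missing from an acquisition point") from exc
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("mean signals are degenerate (no x-variance)")
    fit = stats.linregress(x, y)
    n = x.size
    tcrit = float(stats.t.ppf(0.975, n - 2))
    slope_ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    icpt_ci = (
        fit.intercept - tcrit * fit.intercept_stderr,
        fit.intercept + tcrit * fit.intercept_stderr,
    )
    if fit.slope < 0:
        warnings.warn(
            f"negative SFI-vs-SI slope ({fit.slope:.3g}) in band {band!r}; "
            "no oxygenation interpretation",
            stacklevel=2,
        )
    return SeparationResult(
        band=band,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        slope_ci95=(float(slope_ci[0]), float(slope_ci[1])),
        intercept_ci95=(float(icpt_ci[0]), float(icpt_ci[1])),
        n_points=n,
    )


def delta_y_percent(result: SeparationResult, model: BloodModel) -> tuple[float, tuple[float, float]]:
    """Convert a separation slope and its CI into ΔY percent.

    The 95% CI of ΔY is the slope CI scaled by the same linear factor
    1/(2*C1*(1-Y)*TE); refuses negative slopes.
    """
    dy = delta_y_from_slope(model, result.slope) * 100.0
    lo, hi = result.slope_ci95
    ci = (
        lo / model.sensitivity * 100.0,
        hi / model.sensitivity * 100.0,
    )
    return dy, ci
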