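"""Spin-echo blood signal model and conversion of fluctuation to ΔY.

The SE signal of venous blood is ``S = C * exp(-R2 * TE)`` with the
transverse relaxation rate depending quadratically on the oxygen
saturation Y::

    R2 = C1 * (1 - Y)^2 + C2

Linearizing around the baseline saturation gives the working relation

    ΔS / S = 2 * C1 * (1 - Y) * TE * ΔY

so the relative signal fluctuation in a band (the slope of SFI versus mean
signal intensity across slice thicknesses) converts directly to an
oxygenation-fluctuation amplitude ΔY.  C and C2 cancel in the ratio.

Defaults are the 1.5-T venous values: Y = 0.66, C1 = 59 1/s (normal
hematocrit 0.40), TE = 30 ms.

The flow-side arithmetic lives here too: the refocused-slab thickness
``ST - (TE/2)*v`` (blood must see both the 90° and 180° pulses to yield SE
signal), the cardiac peak-to-peak variation of that slab, and its
conversion into a thickness-independent MR signal fluctuation FF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "BloodModel",
    "FlowGeometry",
    "r2_rate",
    "se_signal",
    "slope_from_delta_y",
    "delta_y_from_slope",
    "combine_quadrature",
    "p2p_to_sd",
    "refocused_thickness",
    "cardiac_thickness_variation",
    "flow_fluctuation",
]

#: sqrt(8): converts a sinusoid's peak-to-peak excursion to its SD.
TWO_ROOT_TWO = 2.0 * math.sqrt(2.0)


@dataclass
class BloodModel:
    """Relaxation/oxygenation constants of venous blood.

    Parameters
    ----------
    y_baseline
        Baseline venous oxygen saturation fraction.
    c1
        Quadratic relaxation coefficient, 1/s (field-strength dependent).
    c2
        Constant relaxation offset, 1/s; cancels in ΔY ratios and defaults
        to 0 (kept for forward simulation realism).
    te
        Echo time in seconds.
    hematocrit
        Hematocrit fraction; documents the provenance of ``c1`` only.
    c_scale
        Proportionality constant C of the signal equation (arbitrary units).
    """

    y_baseline: float = 0.66
    c1: float = 59.0
    c2: float = 0.0
    te: float = 0.030
    hematocrit: float = 0.40
    c_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.y_baseline < 1.0:
            raise ValueError("y_baseline must be in (0, 1)")
        if not self.c1 > 0:
            raise ValueError("c1 must be positive")
        if not self.te > 0:
            raise ValueError("te must be positive")

    @property
    def sensitivity(self) -> float:
        """dimensionless gain 2*C1*(1-Y)*TE linking ΔY to ΔS/S."""
        return 2.0 * self.c1 * (1.0 - self.y_baseline) * self.te


def r2_rate(model: BloodModel, y: float) -> float:
    """Transverse relaxation rate R2 = C1*(1-y)^2 + C2, in 1/s."""
    if not 0.0 <= y <= 1.0:
        raise ValueError("oxygen saturation must be in [0, 1]")
    return model.c1 * (1.0 - y) ** 2 + model.c2


def se_signal(model: BloodModel, y: float) -> float:
    """Spin-echo signal S = C * exp(-R2(y) * TE), arbitrary units."""
    return model.c_scale * math.exp(-r2_rate(model, y) * model.te)


def slope_from_delta_y(model: BloodModel, delta_y: float) -> float:
    """Forward linearized model: ΔS/S produced by an oxygenation amplitude ΔY."""
    if delta_y < 0:
        raise ValueError("delta_y must be non-negative")
    return model.sensitivity * delta_y


def delta_y_from_slope(model: BloodModel, slope: float) -> float:
    """Oxygenation-fluctuation amplitude ΔY = slope / (2*C1*(1-Y)*TE).

    ``slope`` is the dimensionless ΔS/S gradient of the SFI-versus-mean-signal
    regression.  Negative slopes are physically meaningless under the
    linearized model and are refused.
    """
    if slope < 0:
        raise ValueError("negative slope has no ΔY interpretation; got %r" % slope)
    denom = model.sensitivity
    if denom <= 0:
        raise ValueError("model sensitivity 2*C1*(1-Y)*TE must be positive")
    return slope / denom


def combine_quadrature(components: Sequence[float]) -> float:
    """Root-sum-of-squares of independent ΔY components (same units in/out)."""
    comps = list(components)
    if not comps:
        raise ValueError("need at least one component")
    if any(c < 0 for c in comps):
        raise ValueError("components must be non-negative")
    return math.sqrt(sum(c * c for c in comps))


def p2p_to_sd(peak_to_peak: float) -> float:
    """SD of a sinusoid from its peak-to-peak excursion: value / (2*sqrt(2))."""
    if peak_to_peak < 0:
        raise ValueError("peak_to_peak must be non-negative")
    return peak_to_peak / TWO_ROOT_TWO


@dataclass
class FlowGeometry:
    """Slice/flow geometry of one acquisition for the flow-fluctuation model.

    Parameters
    ----------
    slice_thickness
        Excited slice thickness in mm (ST).
    velocity
        Mean blood flow velocity in mm/s (v).
    te
        Echo time in seconds.
    mean_signal
        Noise-normalized mean signal intensity of the vessel ROI (SI).
    pulsatile_fraction_p2p
        Peak-to-peak fractional velocity variation over the cardiac cycle
        (±10% → 0.20).
    """

    slice_thickness: float
    velocity: float
    te: float = 0.030
    mean_signal: float = 1.0
    pulsatile_fraction_p2p: float = 0.20

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0 or self.velocity < 0 or self.te <= 0:
            raise ValueError("slice_thickness, te must be positive; velocity >= 0")


def refocused_thickness(geom: FlowGeometry) -> float:
    """Thickness of the slab seeing both RF pulses: ST - (TE/2)*v, in mm.

    Blood moving at v leaves the slice during TE/2 between excitation and
    refocusing; only the remaining slab yields SE signal.
    """
    result = geom.slice_thickness - 0.5 * geom.te * geom.velocity
    if result <= 0:
        raise ValueError(
            f"refocused slab is non-positive ({result:.3g} mm): "
            "slice thinner than the flow displacement over TE/2"
        )
    return result


def cardiac_thickness_variation(geom: FlowGeometry) -> float:
    """Peak-to-peak refocused-slab variation v*(TE/2)*p2p_fraction, in mm."""
    if not 0.0 <= geom.pulsatile_fraction_p2p < 1.0:
        raise ValueError("pulsatile_fraction_p2p must be in [0, 1)")
    return geom.velocity * 0.5 * geom.te * geom.pulsatile_fraction_p2p


def flow_fluctuation(geom: FlowGeometry) -> float:
    """Cardiac flow-driven signal fluctuation FF (SD, signal units).

    ``FF = Δd / (ST - (TE/2)*v) * SI / (2*sqrt(2))`` where Δd is the
    peak-to-peak cardiac variation of the refocused slab.  The fraction is
    the relative signal excursion; 2√2 converts peak-to-peak to SD under a
    sinusoidal pulsation.  FF is independent of slice thickness when SI is
    proportional to the refocused slab, which is why it appears as the
    y-intercept of the separation regression.
    """
    return (
        cardiac_thickness_variation(geom)
        / refocused_thickness(geom)
        * geom.mean_signal
        / TWO_ROOT_TWO
    )
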