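"""Worst-case bound on head-motion contamination of the vessel-ROI fluctuation.

An in-plane shift Δr changes the mean signal of a k-pixel ROI by
``(1/k) Σ ∇S_i · Δr``.  Attributing *all* signal fluctuation in a skull ROI
(which contains a high-contrast bone edge) to motion gives a worst-case
displacement estimate::

    SD_skull = |(1/k) Σ ∇S_i| * |Δr|     →    |Δr| = SD_skull / mean-gradient

The same displacement, multiplied by the *maximum* frame gradient of the
vessel ROI, bounds the motion-induced fluctuation there (SD_motion).  If
SD_motion is below a small fraction (default 10%) of the vessel's
respiratory SFI, head motion is negligible for the oxygenation analysis.

Either total SD or band-limited SFI may be used as the fluctuation input;
the gradient is a per-pixel vector from 4-neighbor central differences,
averaged over ROI pixels *as a vector* before taking the magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionEstimate",
    "NegligibilityDecision",
    "roi_gradient_stats",
    "displacement_from_fluctuation",
    "motion_induced_sd",
    "motion_negligibility",
    "p2p_displacement_mm",
]

TWO_ROOT_TWO = 2.0 * math.sqrt(2.0)


@dataclass
class MotionEstimate:
    """Skull-gradient statistics and derived displacement/fluctuation bounds."""

    mean_grad: float  # |(1/k) Σ ∇S_i| averaged over frames, 1/pixel
    max_grad: float  # frame maximum of the same magnitude, 1/pixel
    sd_skull: float  # fluctuation (SD or SFI) used as motion input
    displacement: float  # |Δr| or |Δr|_r, pixels
    sd_motion: float  # bound on vessel-ROI motion fluctuation
    k: int  # ROI pixel count


@dataclass
class NegligibilityDecision:
    ratio: float
    max_fraction: float
    passes: bool


def roi_gradient_stats(frames: np.ndarray, roi: np.ndarray) -> tuple[float, float]:
    """(mean, max) over frames of the magnitude of the ROI-mean gradient vector.

    Per frame and pixel the gradient is the 4-neighbor central difference
    ``((S[r, c+1] - S[r, c-1])/2, (S[r+1, c] - S[r-1, c])/2)``; the vectors
    are averaged over the k ROI pixels and the magnitude of that mean vector
    is taken.  Every ROI pixel must have all four neighbors in-bounds.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must have shape (rows, cols, n_frames)")
    roi = np.asarray(roi).astype(bool)
    if roi.shape != frames.shape[:2]:
        raise ValueError("ROI shape mismatch")
    rows, cols = np.nonzero(roi)
    if rows.size == 0:
        raise ValueError("ROI is empty")
    nr, nc = frames.shape[:2]
    if rows.min() < 1 or cols.min() < 1 or rows.max() >= nr - 1 or cols.max() >= nc - 1:
        raise ValueError("ROI touches the image border; gradients undefined")
    gx = (frames[rows, cols + 1, :] - frames[rows, cols - 1, :]) / 2.0  # (k, T)
    gy = (frames[rows + 1, cols, :] - frames[rows - 1, cols, :]) / 2.0
    mag = np.hypot(gx.mean(axis=0), gy.mean(axis=0))  # per frame
    return float(mag.mean()), float(mag.max())


def displacement_from_fluctuation(fluctuation: float, mean_grad: float) -> float:
    """Worst-case displacement |Δr| = fluctuation / mean gradient, in pixels.

    ``fluctuation`` may be a total SD or a band-limited SFI (then the result
    is the displacement at that band, e.g. the respiratory shift |Δr|_r).
    """
    if fluctuation < 0:
        raise ValueError("fluctuation must be non-negative")
    if mean_grad <= 0:
        raise ValueError("mean gradient must be positive (motion unobservable)")
    return fluctuation / mean_grad


def motion_induced_sd(max_grad: float, displacement: float) -> float:
    """Worst-case motion-induced fluctuation: max frame gradient × displacement."""
    if max_grad < 0 or displacement < 0:
        raise ValueError("inputs must be non-negative")
    return max_grad * displacement


def motion_negligibility(
    sd_motion: float,
    vessel_sfi: float,
    max_fraction: float = 0.10,
) -> NegligibilityDecision:
    """Is the motion bound at most ``max_fraction`` of the vessel band SFI?"""
    if vessel_sfi <= 0:
        raise ValueError("vessel SFI must be positive")
    ratio = sd_motion / vessel_sfi
    return NegligibilityDecision(ratio=ratio, max_fraction=max_fraction, passes=ratio <= max_fraction)


def p2p_displacement_mm(displacement_sd: float, fov_mm: float, matrix: int) -> float:
    """Peak-to-peak motion excursion in mm: SD × 2√2 × (FOV / matrix).

    Assumes sinusoidal motion (SD → peak-to-peak via 2√2) and square pixels
    of size FOV/matrix.
    """
    if displacement_sd < 0 or fov_mm <= 0 or matrix <= 0:
        raise ValueError("invalid inputs")
    return displacement_sd * TWO_ROOT_TWO * fov_mm / matrix
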