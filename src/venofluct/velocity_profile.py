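"""Along-vessel velocity profiles: block averaging, spatial derivative, inflow check.

The constant-vessel-geometry assumption behind the slice-thickness
separation is checked against a phase-contrast velocity map of the vessel:
the map is reduced to block-mean velocities along the vessel (default 30
blocks), and slice locations where the along-vessel velocity derivative is
large are excluded.  A separate sanity check verifies the inflow-refresh
condition: the slowest blood must traverse more than the maximum slice
thickness per TR, so that every excitation sees fully relaxed spins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VelocityProfile",
    "InflowCheck",
    "block_average",
    "derivative_at",
    "derivatives",
    "inflow_refresh_check",
]

DEFAULT_N_BLOCKS = 30


@dataclass
class VelocityProfile:
    """Block-mean velocities (cm/s) ordered upstream → downstream."""

    block_means: np.ndarray
    block_length: float | None = None  # mm, metadata only

    def __post_init__(self) -> None:
        self.block_means = np.asarray(self.block_means, dtype=float)
        if self.block_means.ndim != 1 or self.block_means.size < 1:
            raise ValueError("profile needs >= 1 block")
        if not np.all(np.isfinite(self.block_means)):
            raise ValueError("block velocities must be finite")

    @property
    def n_blocks(self) -> int:
        return self.block_means.size


@dataclass
class InflowCheck:
    displacement_mm: float
    max_slice_thickness_mm: float
    passes: bool


def block_average(velocity_map: np.ndarray, block_masks: list[np.ndarray]) -> VelocityProfile:
    """Per-block arithmetic mean of velocity pixels.

    ``block_masks`` must be ordered along the vessel (upstream first).
    """
    vmap = np.asarray(velocity_map, dtype=float)
    if vmap.ndim != 2:
        raise ValueError("velocity map must be 2-D")
    means = []
    for i, mask in enumerate(block_masks):
        m = np.asarray(mask).astype(bool)
        if m.shape != vmap.shape:
            raise ValueError(f"block mask {i} shape mismatch")
        if not m.any():
            raise ValueError(f"block {i} is empty")
        means.append(float(vmap[m].mean()))
    return VelocityProfile(np.array(means))


def derivative_at(profile: VelocityProfile, block_index: int, window: int = 1) -> float:
    """Along-vessel velocity derivative at a block, in cm/s per block index.

    ``window=1`` uses a central difference ``(v[i+1] - v[i-1])/2`` at
    interior blocks and a one-sided difference at the ends.  ``window>1``
    fits a local line over blocks ``i-window .. i+window`` (clipped to the
    profile) and returns its slope — a tangent to a smoothed profile.
    """
    v = profile.block_means
    n = v.size
    if n < 2:
        raise ValueError("derivative needs >= 2 blocks")
    if not 0 <= block_index < n:
        raise IndexError(f"block index {block_index} out of range [0, {n})")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        if block_index == 0:
            return float(v[1] - v[0])
        if block_index == n - 1:
            return float(v[-1] - v[-2])
        return float((v[block_index + 1] - v[block_index - 1]) / 2.0)
    lo = max(0, block_index - window)
    hi = min(n - 1, block_index + window)
    idx = np.arange(lo, hi + 1)
    return float(np.polyfit(idx, v[idx], 1)[0])


def derivatives(profile: VelocityProfile, window: int = 1) -> np.ndarray:
    """Derivative at every block (convenience over :func:`derivative_at`)."""
    return np.array(
        [derivative_at(profile, i, window=window) for i in range(profile.n_blocks)]
    )


def inflow_refresh_check(
    min_velocity_cm_s: float,
    tr_s: float,
    max_slice_thickness_mm: float,
) -> InflowCheck:
    """Does the slowest blood traverse more than the thickest slice per TR?

    Passes iff ``min_velocity * TR`` (converted to mm) strictly exceeds the
    maximum slice thickness, guaranteeing complete spin refreshment.
    """
    if min_velocity_cm_s <= 0 or tr_s <= 0 or max_slice_thickness_mm <= 0:
        raise ValueError("all inputs must be positive")
    displacement_mm = min_velocity_cm_s * 10.0 * tr_s
    return InflowCheck(
        displacement_mm=displacement_mm,
        max_slice_thickness_mm=max_slice_thickness_mm,
        passes=displacement_mm > max_slice_thickness_mm,
    )
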