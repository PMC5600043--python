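"""Band-limited spectral fluctuation statistics for ROI time series.

The temporal fluctuation of an MR signal ``S(n)`` is summarized by its
population standard deviation.  By Parseval's theorem the same quantity can
be read off the discrete Fourier transform ``X(m)`` of the mean-subtracted
series ``x(n) = S(n) - S_average``::

    SD^2 = (1/N^2) * sum_m |X(m)|^2

Restricting the sum to the bins of a frequency band [w1, w2] defines the
spectral fluctuation intensity (SFI) — the standard deviation of the signal
component living in that band.  Because ``x(n)`` is real the power spectrum
is symmetric, so the SFI is computed from positive-frequency bins with a
factor 2 inside the root (the Nyquist bin, when present, has no distinct
mirror and is counted once).

Conventions fixed here and relied on elsewhere:

* unnormalized forward DFT (``numpy.fft.fft``), so Parseval holds in the
  form above;
* population SD (divide by N);
* the mean is subtracted before transforming and the DC bin is excluded
  from every band — no detrending or windowing beyond that;
* a bin belongs to a band when its center frequency f satisfies
  ``lo <= f <= hi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateNoiseError, EmptyBandError, RoiConflictError

__all__ = [
    "RoiTimeSeries",
    "BandSpectrum",
    "FrequencyBand",
    "LOW_BAND",
    "RESPIRATORY_BAND",
    "cardiac_band",
    "normalize_frames",
    "extract_series",
    "select_vessel_roi",
    "time_domain_sd",
    "power_spectrum",
    "sfi",
    "noise_floor_per_bin",
    "find_cardiac_center",
]

#: Number of initial non-equilibrium frames dropped by default (2 s at TR 250 ms).
DEFAULT_N_TRANSIENT = 8

#: Number of vessel pixels retained by default when selecting the ROI.
DEFAULT_VESSEL_PIXELS = 11


@dataclass(frozen=True)
class FrequencyBand:
    """A closed frequency interval ``[lo, hi]`` in Hz with a label."""

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi):
            raise ValueError(f"band requires 0 <= lo < hi, got [{self.lo}, {self.hi}]")


#: Low-frequency band (<0.1 Hz); DC is excluded bin-wise, so lo=0 is safe.
LOW_BAND = FrequencyBand(0.0, 0.1, "low")
#: Respiratory band, 0.2–0.5 Hz.
RESPIRATORY_BAND = FrequencyBand(0.2, 0.5, "respiratory")


def cardiac_band(center_hz: float, half_width_hz: float = 0.2) -> FrequencyBand:
    """Cardiac band centered on the individual pulsation peak (default ±0.2 Hz)."""
    return FrequencyBand(center_hz - half_width_hz, center_hz + half_width_hz, "cardiac")


@dataclass
class RoiTimeSeries:
    """Noise-normalized signal samples from one ROI of one acquisition.

    Parameters
    ----------
    values
        Per-frame ROI-mean signal, dimensionless after corner-noise
        normalization, with transient frames already removed.
    tr
        Repetition time in seconds (sampling interval).
    n_excluded_transient
        Number of initial non-equilibrium frames dropped before ``values``.
    roi_id
        Free-form label for bookkeeping.
    """

    values: np.ndarray
    tr: float
    n_excluded_transient: int = 0
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("time series must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclass
class BandSpectrum:
    """Power spectrum ``|X(m)|^2`` of a mean-subtracted series plus bin metadata."""

    power: np.ndarray  # full length-N array, bin m at frequency m/(N*tr)
    freq_resolution: float  # Hz per bin, 1/(N*tr)
    nyquist: float  # Hz, 1/(2*tr)
    n_samples: int

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.size != self.n_samples:
            raise ValueError("power array length must equal n_samples")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")

    @property
    def positive_freqs(self) -> np.ndarray:
        """Center frequencies of bins 1..floor(N/2), in Hz."""
        return np.arange(1, self.n_samples // 2 + 1) * self.freq_resolution


def _as_bool_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool:
        m = m.astype(bool)
    if m.shape != shape:
        raise ValueError(f"mask shape {m.shape} does not match image shape {shape}")
    return m


def normalize_frames(
    frames: np.ndarray,
    noise_rois: list[np.ndarray],
    pixels_per_roi: int | None = None,
    exclude_rois: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    """Divide every pixel of every frame by the corner-noise reference level.

    The receiver gain differs between acquisitions (it is auto-adjusted per
    slice thickness), so each acquisition is rescaled by one scalar: the mean
    magnitude over all noise-ROI pixels across all frames.

    Parameters
    ----------
    frames
        Image stack of shape (rows, cols, n_frames).
    noise_rois
        Boolean masks (rows, cols), conventionally four corner regions.
    pixels_per_roi
        If given, each noise ROI must contain exactly this many pixels.
    exclude_rois
        Masks (e.g. the vessel ROI) that must not overlap any noise ROI.

    Returns
    -------
    (normalized_frames, noise_mean)

    Raises
    ------
    DegenerateNoiseError
        If the noise reference is zero or negligibly small.
    RoiConflictError
        If noise ROIs overlap each other or an excluded ROI.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must have shape (rows, cols, n_frames)")
    shape = frames.shape[:2]
    masks = [_as_bool_mask(m, shape) for m in noise_rois]
    if not masks:
        raise ValueError("at least one noise ROI is required")
    for i, m in enumerate(masks):
        count = int(m.sum())
        if count == 0:
            raise ValueError(f"noise ROI {i} is empty")
        if pixels_per_roi is not None and count != pixels_per_roi:
            raise ValueError(
                f"noise ROI {i} has {count} pixels, expected {pixels_per_roi}"
            )
    union = np.zeros(shape, dtype=bool)
    for i, m in enumerate(masks):
        if np.any(union & m):
            raise RoiConflictError(f"noise ROI {i} overlaps another noise ROI")
        union |= m
    for j, ex in enumerate(exclude_rois or []):
        ex = _as_bool_mask(ex, shape)
        if np.any(union & ex):
            raise RoiConflictError(f"noise ROIs overlap excluded ROI {j}")

    noise_mean = float(np.abs(frames[union]).mean())
    scale_ref = float(np.abs(frames).max()) or 1.0
    if noise_mean <= 0 or noise_mean < 1e-12 * scale_ref:
        raise DegenerateNoiseError(
            f"noise reference level {noise_mean!r} is degenerate"
        )
    return frames / noise_mean, noise_mean


def extract_series(
    frames: np.ndarray,
    roi: np.ndarray,
    tr: float,
    n_transient: int = DEFAULT_N_TRANSIENT,
    roi_id: str = "",
) -> RoiTimeSeries:
    """Per-frame ROI-mean signal with the initial transient frames dropped."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must have shape (rows, cols, n_frames)")
    roi = _as_bool_mask(roi, frames.shape[:2])
    if not roi.any():
        raise ValueError("ROI is empty")
    n_frames = frames.shape[2]
    if not 0 <= n_transient < n_frames:
        raise ValueError(f"n_transient={n_transient} out of range for {n_frames} frames")
    series = frames[roi].mean(axis=0)[n_transient:]
    return RoiTimeSeries(series, tr=tr, n_excluded_transient=n_transient, roi_id=roi_id)


def select_vessel_roi(
    frames: np.ndarray,
    search_mask: np.ndarray,
    n_pixels: int = DEFAULT_VESSEL_PIXELS,
) -> np.ndarray:
    """Mask of the ``n_pixels`` brightest pixels within ``search_mask``.

    Brightness is the temporal mean when a stack is given (a single 2-D frame
    is accepted too).  Ties are broken deterministically by row-major pixel
    index, lower index first.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        mean_img = frames
    elif frames.ndim == 3:
        mean_img = frames.mean(axis=2)
    else:
        raise ValueError("expected a 2-D frame or a (rows, cols, n_frames) stack")
    search_mask = _as_bool_mask(search_mask, mean_img.shape)
    flat_idx = np.flatnonzero(search_mask.ravel())
    if flat_idx.size < n_pixels:
        raise ValueError(
            f"search mask has {flat_idx.size} pixels, fewer than requested {n_pixels}"
        )
    intensities = mean_img.ravel()[flat_idx]
    # lexsort: last key is primary -> sort by -intensity, tie-break on flat index
    order = np.lexsort((flat_idx, -intensities))
    chosen = flat_idx[order[:n_pixels]]
    roi = np.zeros(mean_img.shape, dtype=bool)
    roi.ravel()[chosen] = True
    return roi


def time_domain_sd(series: RoiTimeSeries) -> float:
    """Population standard deviation (divide by N) of the series."""
    x = series.values
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def power_spectrum(series: RoiTimeSeries) -> BandSpectrum:
    """Unnormalized-DFT power spectrum of the mean-subtracted series.

    Satisfies Parseval's identity ``sum |x(n)|^2 = (1/N) sum |X(m)|^2``.
    """
    x = series.values - series.values.mean()
    n = x.size
    X = np.fft.fft(x)
    return BandSpectrum(
        power=np.abs(X) ** 2,
        freq_resolution=1.0 / (n * series.tr),
        nyquist=1.0 / (2.0 * series.tr),
        n_samples=n,
    )


def _band_bins(spectrum: BandSpectrum, band: FrequencyBand) -> tuple[np.ndarray, np.ndarray]:
    """Positive-frequency bin indices whose centers fall in the band, with weights.

    The DC bin is always excluded; the Nyquist bin (even N) gets weight 1/2
    because it has no distinct mirror image to double.
    """
    df = spectrum.freq_resolution
    n = spectrum.n_samples
    m_max = n // 2
    # tiny relative tolerance so exact band edges at bin centers are inclusive
    m_lo = max(1, int(np.ceil(band.lo / df - 1e-9)))
    m_hi = min(m_max, int(np.floor(band.hi / df + 1e-9)))
    if m_hi < m_lo:
        raise EmptyBandError(
            f"band [{band.lo}, {band.hi}] Hz contains no bins "
            f"(resolution {df:.5g} Hz, nyquist {spectrum.nyquist:.5g} Hz)"
        )
    bins = np.arange(m_lo, m_hi + 1)
    weights = np.ones(bins.size)
    if n % 2 == 0 and bins[-1] == n // 2:
        weights[-1] = 0.5
    return bins, weights


def sfi(
    spectrum: BandSpectrum,
    band: FrequencyBand,
    noise_power_per_bin: float = 0.0,
) -> float:
    """Spectral fluctuation intensity over a band.

    ``SFI = sqrt( (2/N^2) * sum_{m in band, m>0} |X(m)|^2 )`` where the sum
    runs over positive-frequency bins and the factor 2 accounts for the
    mirrored negative frequencies of a real signal.  Equals the time-domain
    SD when the band spans all positive frequencies.

    Parameters
    ----------
    noise_power_per_bin
        Optional white-noise floor (per-bin expected power, e.g. from
        :func:`noise_floor_per_bin`) subtracted from the band power before
        the square root; the result is clipped at zero.
    """
    bins, weights = _band_bins(spectrum, band)
    total = float(np.dot(weights, spectrum.power[bins]))
    if noise_power_per_bin:
        total -= noise_power_per_bin * float(weights.sum())
    total = max(total, 0.0)
    n = spectrum.n_samples
    return float(np.sqrt(2.0 * total / n**2))


def noise_floor_per_bin(
    spectrum: BandSpectrum,
    exclude_bands: list[FrequencyBand] | None = None,
) -> float:
    """Robust estimate of the white-noise power per spectral bin.

    Uses the median of positive-frequency bin powers outside the excluded
    (signal) bands; for complex-Gaussian bins the power is exponentially
    distributed, so the median is rescaled by 1/ln 2 to estimate the mean.
    Returns 0.0 if fewer than 8 quiet bins are available.
    """
    n = spectrum.n_samples
    m_max = n // 2
    keep = np.ones(m_max, dtype=bool)  # bins 1..m_max
    for band in exclude_bands or []:
        try:
            bins, _ = _band_bins(spectrum, band)
        except EmptyBandError:
            continue
        keep[bins - 1] = False
    quiet = spectrum.power[1 : m_max + 1][keep]
    if quiet.size < 8:
        return 0.0
    return float(np.median(quiet) / np.log(2.0))


def find_cardiac_center(
    spectrum: BandSpectrum,
    search_lo: float = 0.6,
    search_hi: float = 1.6,
) -> float:
    """Frequency of the maximum-power bin in the search window (Hz).

    The cardiac pulsation peak sits around 1 Hz; the cardiac band is then
    centered on the individual peak.  Ties break to the lowest frequency.
    """
    bins, _ = _band_bins(spectrum, FrequencyBand(search_lo, search_hi, "search"))
    best = bins[int(np.argmax(spectrum.power[bins]))]
    return float(best * spectrum.freq_resolution)
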