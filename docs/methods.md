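# Methods

## Signal model and assumptions

The package analyzes the temporal fluctuation of the spin-echo EPI signal
of venous blood in a vessel imaged perpendicular to the slice. The working
model has three parts:

1. **Relaxation.** S = C·exp(−R₂·TE), R₂ = C₁(1−Y)² + C₂, with Y the blood
   oxygen saturation. Linearized about the baseline Y₀ this gives
   ΔS/S = 2C₁(1−Y₀)TE·ΔY ("sensitivity" below). C and C₂ cancel in the
   ratio, so neither needs to be known.
2. **Inflow geometry.** Only blood that experiences both the 90° and 180°
   pulses contributes: the refocused slab is ST − (TE/2)·v for slice
   thickness ST and through-plane velocity v. The mean vessel signal SI is
   proportional to this slab, which is the lever for the separation: an
   oxygenation modulation scales with SI, a velocity modulation does not.
3. **Stationarity.** Over one 45-s acquisition the vessel cross-section,
   baseline saturation and band frequencies are treated as constant; the
   three physiological processes (low-frequency vasomotion, respiration,
   cardiac pulsation) are narrow-band and mutually independent.

Assumption 2 requires constant vessel geometry over the thickest slab.
This is screened, not assumed: a slice location enters the pooled
regression only if mean signal is linear in thickness (R² > 0.77) and the
along-vessel velocity derivative is within ±0.1 (both thresholds
configurable).

## The SFI statistic

For a series of N retained samples the spectral fluctuation intensity over
a band is the square root of (2/N²) times the band-summed power of the
unnormalized DFT of the mean-subtracted series. Numerical conventions:

* population SD (÷N), so the full-band SFI equals the time-domain SD
  exactly (Parseval);
* DC is excluded from every band (the mean is already removed); a bin
  belongs to a band when its center frequency lies in the closed interval;
* for even N the Nyquist bin has no mirror and is counted once (half
  weight inside the doubled sum);
* no windowing, tapering or detrending beyond mean subtraction.

The cardiac band is auto-centered on the maximum-power bin in a 0.6–1.6 Hz
search window (ties to the lowest frequency); a fixed center can be
configured instead.

An optional white-noise floor correction estimates the per-bin noise power
as median/ln 2 of the out-of-band positive-frequency bins (the median of an
exponential distribution is ln 2 times its mean, and the median is robust
to residual narrow-band peaks) and subtracts bin-count × floor from the
band power, clipped at zero. It is off in the plain pipeline — the
reference analysis applies none — and on by default in the synthetic
recovery harness whenever noise is injected, where it removes the upward
SFI bias of the in-band noise power.

## Separation regression and confidence intervals

Band SFI is regressed on mean signal intensity by ordinary least squares,
pooling the retained acquisitions of all locations and subjects. The slope
is ΔS/S, the intercept the velocity-fluctuation component. 95% confidence
intervals are t-based (n−2 degrees of freedom) from the OLS standard
errors; the ΔY interval is the slope interval scaled by 1/sensitivity, a
linear transformation that is exact for the ratio of a fixed constant.
Whether a reported "mean ± 95% CI" should be a pooled-slope CI or an
across-location dispersion is genuinely open; the pooled-slope convention
is used and recorded in the output. Negative fitted slopes are reported
with a warning but refused by the ΔY conversion (the linearized model
admits no negative fluctuation amplitude).

## Motion bound

The gradient of each ROI pixel is the 4-neighbor central difference; the
pixel vectors are averaged *as vectors* over the ROI and the magnitude of
the mean vector taken, per frame. Attributing all skull-ROI fluctuation
(SD or band SFI) to rigid in-plane shift gives the worst-case displacement
|Δr| = fluctuation / mean-gradient; multiplying by the *maximum* frame
gradient of the vessel ROI bounds the motion-induced vessel fluctuation.
The bound is conservative by construction — every step picks the worst
case — so passing the ≤10%-of-respiratory-SFI check is meaningful, while
failing it does not prove motion contamination.

## Synthetic-data generator

`SimulationScenario` defaults are the study conditions: thicknesses
7/9/11/13/15 mm, TR 0.25 s, 45 s (180 frames, first 8 transient, N = 172),
TE 30 ms, band amplitudes ΔY = 1.8/1.2/2.4 % at 0.06/0.30/1.16 Hz, mean
sinus velocity 97.2 mm/s, velocity-fluctuation amplitude 0.35 signal units
at the cardiac frequency. Two constants have no reported value and were fixed
once on physical grounds: `signal_per_mm` = 2.5 normalized units/mm, which
places SI and the respiratory SFI (≈0.5 at 15 mm) in the reported range,
and `noise_sd` = 0.15 normalized units (≈0.6 % of SI), consistent with the
observation that the noise/skull spectrum is ~1 % of the sinus spectrum.

Design choices that matter for testing:

* **Linearized additive modulation.** The oxygenation term is
  SI·(1 + Σ_b √2·a_b·sin(2πf_b t + φ_b)) with a_b = sensitivity·ΔY_b. The
  √2 makes ΔY an SD-type amplitude, matching what the analysis recovers. A
  product of per-band factors would create intermodulation lines inside
  the analysis bands (~2×10⁻⁴ relative SFI error), destroying closed-form
  exactness; a `nonlinear=True` switch re-exponentiates the relaxation
  model per time point for linearization-error studies (second-order
  deviation ≲1 % at the default modulation depth).
* **Coherent velocity term.** The thickness-independent velocity sinusoid
  is phase-locked to the cardiac oxygenation modulation (both ride the
  same pulse), which is what makes the linear-additive separation model
  (SFI = slope·SI + intercept) hold exactly; with
  `velocity_phase_locked=False` the two same-frequency components add in
  quadrature with random phase and the intercept is no longer the injected
  amplitude even without noise.
* **On-bin frequencies** (snap to the N = 172 grid) by default so sinusoid
  SFIs have exact closed forms; off-bin leakage is an opt-in stressor
  (`on_bin=False`).
* **Gaussian signal noise.** Noise is additive Gaussian on the ROI series
  (optionally scaled to a fraction of SI); the image generator's background
  uses magnitude (half-normal) noise of known mean so the corner-noise
  normalization has a ground truth. Rician statistics at the vessel are
  not simulated — the vessel operates far above the noise floor.
* **Rigid motion** is a sinusoidal in-plane x-shift at the respiratory
  frequency applied by linear interpolation; the static skull block holds
  a high-contrast ramp so its ROI-mean gradient vector is non-zero (an
  alternating pattern would cancel under the central-difference stencil).

What passing synthetic tests shows: the estimator chain is consistent
(exact inversion of its own forward model at zero noise), unbiased after
floor correction, and correctly calibrated (CI coverage). What it does not
show: robustness to broadband physiological spectra, off-bin leakage,
Rician noise, coil-sensitivity structure, or non-rigid motion — real
acquisitions differ in all of these.

## Accuracy versus noise

Recovery error scales linearly with the noise-to-signal ratio. Measured
median relative ΔY errors over 200 seeded experiments (floor correction
on): at σ/SI = 0.5 % — low 2.0 %, respiratory 2.7 %, cardiac 1.6 %; at
σ/SI = 5 % — low 20 %, respiratory 50 %, cardiac 19 %. The respiratory
band is the hardest case: its relative modulation is only
sensitivity×0.012 ≈ 1.4 % of SI, and with N = 172 samples the
amplitude-estimation floor of *any* estimator at σ/SI = 5 % is ≈26 % per
acquisition (σ√(2/N) against a √2·1.4 %·SI amplitude), so percent-level ΔY
recovery at that noise level is information-theoretically out of reach for
a 45-s acquisition. At the default (reported-range) SNR the chain recovers all
three bands to a few percent.

## Degenerate inputs and tie-breaks

Zero or near-zero corner-noise reference → explicit degenerate-noise
error; overlapping ROIs → conflict error; bands containing no bins →
empty-band error; vessel-ROI brightness ties → row-major pixel order;
equal cardiac peaks → lowest frequency; velocity-profile derivative uses a
central difference at interior blocks, one-sided at the ends, with an
optional ±w-block local-line fit (`window > 1`) since a tangent to a
smoothed profile is equally defensible; the inflow-refresh check uses a
strict inequality (displacement must exceed the thickest slice).

## Problem sizes

Synthetic experiments use the full study geometry (5 thicknesses × 172
retained samples); Monte-Carlo suites use 200 seeded experiments for
recovery/coverage statistics and 100 series for spectral identities. Image
stacks for pipeline tests are 48×48×180 with a 6×6 corner-noise ROI
layout, an 11-pixel vessel and a 16-pixel skull block — the reference
128×128 matrix scaled down with ROI pixel counts preserved where they
matter (vessel, skull).
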