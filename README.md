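# venofluct

Non-invasive quantification of the resting-state fluctuation of cerebral
venous blood oxygenation from spin-echo EPI time series.

Respiratory variation of arterial CO₂ makes cerebral arterioles dilate and
constrict; that vasomotion modulates the oxygen saturation Y of the venous
blood draining the brain. Because the spin-echo MR signal of blood depends
on Y through its transverse relaxation rate, the oxygenation fluctuation can
be read out of the signal fluctuation of a large vein — here the superior
sagittal sinus — without any drug or gas challenge. `venofluct` implements
that measurement chain for researchers working with multi-slice-thickness
SE-EPI acquisitions (and provides a matched synthetic-data generator so the
whole chain can be exercised without scanner data).

## Method

**Spectral fluctuation intensity (SFI).** For a noise-normalized ROI series
S(n), n = 1…N, the fluctuation confined to a frequency band [ω₁, ω₂] is

    SFI = sqrt( (2/N²) · Σ_{m ∈ band, m>0} |X(m)|² ),

where X(m) is the unnormalized DFT of S(n) − S̄. By Parseval's theorem the
SFI over all positive frequencies equals the time-domain population SD.
Three bands are analyzed: low (< 0.1 Hz), respiratory (0.2–0.5 Hz), and
cardiac (individual pulsation peak ± 0.2 Hz, located automatically).

**Slice-thickness separation.** The mean vessel signal SI grows with slice
thickness (more refocused blood), and so does the oxygenation-driven
fluctuation — it is a fixed relative modulation ΔS/S. Fluctuation caused by
blood-velocity variation is thickness-independent. Regressing band SFI on
SI across slice thicknesses (7–15 mm) therefore separates the two: the
slope is ΔS/S, the y-intercept the velocity component. Slice locations are
screened first: the SI-versus-thickness linearity must give R² > 0.77 and
the along-vessel velocity derivative must satisfy |d| ≤ 0.1 (constant
vessel geometry).

**Relaxation model.** With S = C·exp(−R₂·TE) and R₂ = C₁(1−Y)² + C₂,
linearization gives ΔS/S = 2·C₁·(1−Y)·TE·ΔY, so the regression slope
converts directly into the oxygenation-fluctuation amplitude

    ΔY = slope / (2·C₁·(1−Y)·TE),

using Y = 0.66, C₁ = 59 s⁻¹ (1.5 T, hematocrit 0.40) and TE = 30 ms.

**Artifact bounds.** A worst-case head-motion bound attributes all skull-ROI
fluctuation to in-plane displacement via SD_skull = |(1/k)Σ∇Sᵢ|·|Δr|, and a
flow model converts the cardiac velocity pulsation into the expected
thickness-independent signal fluctuation FF = Δd/(ST − TE/2·v) · SI/(2√2).

## Worked example

Converting the per-band separation slopes of a resting-state sinus
experiment (low 0.022, respiratory 0.015, cardiac 0.029):

```python
>>> from venofluct import BloodModel, delta_y_from_slope, combine_quadrature
>>> m = BloodModel()                       # Y=0.66, C1=59 /s, TE=30 ms
>>> [round(delta_y_from_slope(m, s) * 100, 1) for s in (0.022, 0.015, 0.029)]
[1.8, 1.2, 2.4]
```

so the venous oxygenation fluctuates by 1.2 % at the respiratory frequency
(the vasomotor index), 1.8 % at low frequencies and 2.4 % at the cardiac
frequency; their quadrature total is 3.27 % ≈ 3.3 %.

A full synthetic experiment — five slice thicknesses, known injected
amplitudes, realistic noise — and its recovery:

```python
from venofluct.synth import SimulationScenario, end_to_end_recovery

report = end_to_end_recovery(SimulationScenario(seed=42))
```

whose report fields, printed per band, read:

```text
low          injected 1.8%  recovered 1.61% (95% CI 1.43-1.80%)
respiratory  injected 1.2%  recovered 1.15% (95% CI 0.84-1.45%)
cardiac      injected 2.4%  recovered 2.35% (95% CI 2.19-2.51%)
velocity intercept (cardiac): injected 0.35, recovered 0.361
```

i.e. the separation regression returns each band's oxygenation amplitude
within its confidence interval and the thickness-independent velocity
component as the intercept.

The command-line interface mirrors this: `venofluct simulate scenario.yaml
out/` writes NIfTI acquisitions with a ground-truth sidecar,
`venofluct analyze config.yaml` runs the full pipeline (normalization, ROI
selection, spectra, screening, separation, ΔY, motion and flow reports),
and `venofluct accept --seed 1` runs the synthetic acceptance harness.

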