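# campariq

Quantification pipeline for **photoconvertible calcium integrator (CaMPARI)
imaging**. CaMPARI proteins convert irreversibly from green to red
fluorescence under ~400-nm light in proportion to intracellular Ca²⁺, so the
per-cell **red-to-green ratio (RGR)** integrates neuronal activity during an
illumination epoch. This package implements the two quantification arms such
experiments need, plus a synthetic two-channel imaging generator that plants
ground truth for every estimated quantity — so the whole pipeline is testable
without a microscope.

**Who it is for:** labs comparing photoconvertible sensor variants (or
characterising a new one) who need the readout statistics, and method
developers who want a fully synthetic benchmark with known answers.

## The statistics

**Photoconversion readout.** Per cell,

```
RGR = ((R_raw − dark_R) − β·(G_raw − dark_G)) / (G_raw − dark_G)
```

where the dark current per channel is the 0.2 percentile of all recorded
pixels, and β is the green-to-red spectral bleed-through fraction (~13–15%),
estimated as the median per-cell red/green ratio on **pre**-photoconversion
images where any red signal is pure contamination. Cell RGRs are pooled
across fields of view before taking the median. Downstream:

* **Light dose**: `power × pulses × pulse duration / spot area`, in mJ/mm²
  (the standard protocol — 200 mW, 40 × 1-s pulses, 7-mm spot — gives
  ≈ 208 mJ/mm²).
* **Dose–response**: zero-intercept linear fit, `slope = Σxy / Σx²`, with a
  t-based test and 95% CI on n−1 degrees of freedom.
* **Dual-wavelength ratio**: per-recording ratio of median RGR at 1,040 vs
  1,000 nm excitation (the red species is excited far more efficiently at
  the longer wavelength).
* **Sensitivity index**: `d′ = (μ_stim − μ_ref) / √(0.5(σ²_stim + σ²_ref))`
  between stimulated (e.g. V1) and reference (e.g. S1) cell populations.

**Dynamic recording.** CaMPARI's green channel is a *negative* GECI —
fluorescence dips when Ca²⁺ rises. Per cell: divisive degree-7 polynomial
bleach correction; per trial, `F_base` = mean of the 0.66 s before grating
onset and `F_resp` = mean of the lowest 25% of samples during the 4-s
grating; `ΔF/F₀ = (F_resp − F_base)/F_base` (negative for responses). Cells
are **tuned** if a baseline-vs-response ANOVA gives p < 0.01 and **oriented**
if, additionally, an 8-direction ANOVA on responses gives p < 0.01.

## Worked example

```bash
campariq run-all --config examples/demo_config.yaml --out demo_out
```

simulates both arms end to end (~6 s on one CPU) and prints, among others:

```
"bleedthrough_1000nm": {"planted": 0.131, "estimated": 0.13098},
"bleedthrough_1040nm": {"planted": 0.146, "estimated": 0.14606},
"dose_response": {"planted_slope": 0.00079, "fitted_slope": 0.000744,
                  "ci95": [0.000696, 0.000792], "p_value": 2.9e-09},
"wavelength_ratio": {"planted": 9.05, "mean": 9.054, "sd": 0.024},
"sensitivity_index": {"planted": 2.26, "estimated": 2.300},
"dynamic": {"fraction_tuned": 1.0, "fraction_oriented": 0.125,
            "planted_fraction_tuned": 0.125, ...}
```

Reading the numbers: the planted bleed-through fractions, dose–response
slope, dual-wavelength ratio and d′ are all re-estimated by the full
image-level pipeline to within their sampling error (the fitted slope's 95%
CI covers the plant). In the dynamic arm the *oriented* fraction recovers
the planted 12.5% of direction-tuned cells, while the *tuned* fraction
saturates at 1.0 — the lowest-25% response statistic is biased low under
noise, which inflates the baseline-vs-response test on every cell. This is a
property of that estimator, reproduced deliberately; see
`docs/methods.md`. Output directory contents: per-cell tables (CSV), a JSON
report, dose–response and amplitude-CDF figures, and a checksum manifest
(identical config + seed ⇒ identical checksums).

Individual stages are also available as `campariq simulate pc`,
`campariq simulate dynamic`, `campariq pc-analyze`, `campariq dyn-analyze`,
or directly as library functions (see `campariq/__init__.py`).

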