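# Methods

## The measurement model

A CaMPARI-expressing cell carries a total fluorophore amount that is split
between a green and a red species. Photoconversion moves amount from green
to red: after cumulative light dose *D* (mJ/mm²), a cell with relative
calcium load *a* has a true red/green species ratio

    r(D) = (k_base + k_act · a) · D

with `k_base` the Ca²⁺-independent background conversion rate and `k_act`
the activity-dependent rate. Increments from successive illumination epochs
add, and the total species amount is conserved (green = total/(1+r),
red = total·r/(1+r)), so conversion never creates signal. The linear-in-dose
form is the small-converted-fraction regime in which these sensors are
operated.

Two-photon readout at excitation wavelength λ and power *P* produces
per-pixel signals

    green = dark_G + e_G(λ)·P²·g + ε
    red   = dark_R + e_R(λ)·P²·ρ + β(λ)·e_G(λ)·P²·g + ε

where *g*, *ρ* are green/red species densities, `e_G`, `e_R` are
species-specific excitation efficiencies, β is the green-to-red emission
bleed-through, and ε is zero-mean Gaussian noise with variance proportional
to the dark-free signal (`noise_scale` = variance/mean, default 1 —
shot-noise-like). The *P²* dependence is the two-photon excitation law and
is why green brightness comparisons are normalised by power squared.
Because the noise is signal-proportional, background pixels sit exactly at
the dark offset; no separate read-noise term is modelled.

Under this model the measured, corrected RGR of a cell equals
`(e_R/e_G)(λ) · r`, so the dual-wavelength ratio of median RGRs equals the
ratio of the efficiency ratios at the two wavelengths — that is what the
generator plants when a target ratio (default 9.05 at 1,040/1,000 nm) is
requested. At 1,000 nm the efficiencies are normalised to `e_G = e_R = 1`,
so planted conversion slopes are directly the measured dose–response slopes.

## Estimators and corrections

* **Dark current**: 0.2 percentile of all pixels of a channel, pooled over
  the whole recording (more stable than per-frame, and the estimand is a
  fixed detector offset). Linear interpolation between order statistics,
  so results are bit-reproducible.
* **Bleed-through β**: median over cells of dark-subtracted red/green on
  pre-photoconversion images (median rather than a regression or pixel
  pooling: robust to segmentation outliers). An estimate ≥ 1 raises —
  it signals swapped channels. Defaults plant 13.1% (1,000 nm) and
  14.6% (1,040 nm).
* **RGR**: dark subtraction first, then β·green subtracted from red, then
  the ratio. Cells with green ≤ dark are excluded (not clipped) with a
  logged count. Per-cell channel means are computed before the ratio
  (ratio of means, lower variance than mean of per-pixel ratios), unweighted
  over the footprint, with no neuropil annulus.
* **Pooling**: the population median is taken over cells pooled across all
  fields of view (photoconversion happens in all expressing cells at once,
  so cells — not FOVs — are the sampling unit). Group summaries for
  between-animal tests use one pooled median per recording.
* **Light dose**: `power[mW] × n_pulses × pulse_s / (π·(d/2)²)` with a 7-mm
  spot by default. The unit is mJ/mm² (mW·s = mJ); the standard 200-mW,
  40 × 1-s protocol gives 207.87 ≈ 208. Doses add across events.
* **Zero-intercept fit**: slope = Σxy/Σx², SE from residual variance on
  n−1 df, two-tailed t test against slope 0 and a t-based 95% CI on the
  same df (the natural df for a one-parameter linear model).
* **d′**: difference of group means over the RMS of the two sample
  variances (n−1 denominators), computed per recording by default. It is
  shift- and scale-invariant and antisymmetric under group swap.
* **Group tests**: Wilcoxon rank-sum with the null enumerated exactly
  (all C(n+m, n) assignments of mid-ranks, so ties are handled) when
  min(n) ≤ 8, normal approximation with tie correction above; two-sample
  and paired t-tests via scipy. A paired test on identical vectors returns
  a flagged NaN rather than guessing.

## Dynamic (negative-GECI) analysis

* **Bleach correction** is divisive: a degree-7 polynomial p(t) is fit to
  the full trace and the trace is multiplied by p(0)/p(t), preserving the
  ratio semantics of ΔF/F₀ and the initial brightness scale. A fit that
  touches zero in-range raises — such traces are unusable. The generator's
  bleaching envelope is a single exponential, deliberately *not* a
  polynomial, so recovery tests exercise model mismatch: planted dip depths
  are recovered within 5% for half-lives from 2× to 10× the recording
  length.
* **Windows**: frame counts are `round(seconds × frame_rate)` — 20 baseline
  frames (0.66 s) and 120 response frames (4 s) at 30 Hz. Trials that do
  not fit inside the recording are dropped with a warning.
* **Responses**: `F_base` is the plain mean of the baseline window (the
  minimal reading); `F_resp` is the mean of the k = round(0.25·L) smallest
  response-window samples after a stable sort. ΔF/F₀ is computed on the
  bleach-corrected trace (correction precedes response extraction).
* **Classification**: the tuned test is a one-way ANOVA between the 40
  baseline and 40 response values (two groups; an 8-direction × 2-condition
  16-group mode is available as `anova_mode="by_direction"` but is not the
  default — the 2-group reading is the minimal interpretation of an
  80-value test). The oriented test, run only on tuned cells, is an ANOVA
  over 8 direction groups of 5 responses; both gates use p < 0.01, so
  oriented ⇒ tuned by construction. The preferred direction is the one
  with the most negative mean ΔF/F₀, and a cell's peak amplitude is its
  mean ΔF/F₀ at that direction (robust, unlike a single-trial extreme).

### Bias of the lowest-25% statistic

The mean of the lowest quartile of L i.i.d. noise samples is below the true
mean by ≈ 1.27σ for Gaussian noise, consistently on every trial. Two
consequences, both asserted in the test suite:

1. With the statistic replaced by the plain window mean (diagnostic mode),
   the tuned test holds its nominal 1% false-positive rate on pure-noise
   cells (Monte Carlo, 2,000 null cells, ±0.5 pp).
2. With the lowest-25% statistic and i.i.d. frame noise, nearly *every*
   null cell is classified tuned: the bias shifts all response values, and
   the ANOVA detects the shift. Real recordings contain slow correlated
   fluctuations that inflate the baseline variance and mask much of this
   effect, which is why measured tuned fractions on real data are far below
   1 — the generator makes the estimator's intrinsic bias visible instead
   of hiding it.

The across-direction (oriented) test compares response values only, so the
bias cancels and the planted fraction of direction-tuned cells is recovered.

## The synthetic generator — what it emulates and what it does not

Emulated: disk-shaped green cells over a dark background (log-normal
expression, median 100 a.u.; radius 3–5 px); log-normal per-cell activity
(median 1, σ = 0.5 — the spread behind RGR variability across cells; the
distribution is configurable because real per-cell calcium load
distributions are not identified by population medians); dose-linear
photoconversion; wavelength-dependent excitation; bleed-through; dark
current; shot-like noise; stimulus-locked multiplicative dips with a
circular-Gaussian direction-tuning profile (width 1 direction unit, i.e.
45°); exponential bleaching; 8-direction × 5-repetition drifting-grating
timing (4-s gratings, 4–12-s gray, 30 Hz).

Not emulated: optical PSF and 3-D structure, cell-shape variability, motion
artifacts, neuropil contamination, spike-level calcium kinetics, correlated
(1/f) noise, red-species decay over days. Passing recovery tests therefore
demonstrates the correctness of the estimators under the stated model, not
robustness to segmentation error or motion — those stages are out of scope
(masks are inputs; registration is assumed done).

## Numerical and design choices

* Polynomial fits use numpy's scaled-domain `Polynomial.fit` for
  conditioning; degree 7 with a hard error below 9 samples.
* Quantiles/percentiles: linear interpolation everywhere.
* Seeds: one run seed is fanned out to independent 31-bit child seeds via
  `numpy.random.SeedSequence.spawn`, so stages are independently
  reproducible; identical config + seed reproduce every artifact
  bit-for-bit (checksummed manifest).
* Degenerate inputs: zero within-group variance ANOVA → p = 1 with a
  warning; both-zero-variance d′ → error; all-identical doses → warning
  (slope identifiable, CI fragile).
* Problem sizes in the validation runs — 200 cells for bleed-through
  recovery, 12 single-mouse sessions of 150 cells for the dose–response
  slopes, 10 paired dual-wavelength recordings of 120 cells, 2,000 cells
  per region for d′ — were chosen to keep each recovery's sampling error
  comfortably inside its stated tolerance while running in seconds on one
  CPU.

## Known limitations

* The measured RGR equals the species ratio only up to the optics factor
  `e_R/e_G`; absolute RGR values are comparable across sessions only at a
  fixed wavelength, exactly as with the real sensor.
* The tuned-cell fraction under the default statistic is not interpretable
  on i.i.d.-noise synthetic data (see bias section); use the oriented
  fraction or the diagnostic mean mode for calibration studies.
* The exact rank-sum enumeration is exponential in group size and is
  capped at min(n) = 8; beyond that the tie-corrected normal approximation
  is used.
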