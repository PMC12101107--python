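# Methods

## The measurement model

A pooled 12-h urine collection integrates a continuous excretion process
over its window: one observation is the *window mean* of the instantaneous
excretion rate, not a point sample. Two consequences drive the design:

1. corrected values are anchored at the interval **midpoint** — for any
   smooth rate the window mean equals the rate at the midpoint to second
   order, so midpoint anchoring keeps phase estimates unbiased;
2. a cosine of period τ pooled over windows of length Δ keeps its phase but
   loses amplitude by the factor `sin(ωΔ/2)/(ωΔ/2)`, ω = 2π/τ
   (`pooling_attenuation`). For Δ = 12 h this is 0.637 at τ = 24 h and
   0.971 at τ = 90 h — 12-h pooling nearly halves a circadian amplitude but
   barely touches a half-weekly one. Fits are performed on the pooled values
   as-is; the factor is exposed so fitted amplitudes can be compared with
   generative ones.

Unit regimes: raw concentration (ng/mL), creatinine-corrected (ng/mg,
normalises urinary flow and glomerular filtration) and volume-corrected
(µg/h, normalises hydration). Wider collection windows are aggregated at the
**mass level** (summed analyte mass over summed creatinine mass, or summed
mass over window hours), as if the urine had been collected in one canister;
a mean-of-values mode exists for comparison (`aggregate(..., method="mean")`).
Incomplete tail windows are dropped — a partial pool is not comparable to a
complete one.

## Day–night statistics

Each day interval is paired with the immediately following night interval;
leading night or trailing day intervals are dropped from pairing (but kept
for CV and rhythm analysis), so 63 alternating intervals yield 31 pairs and
55 yield 27. The paired t statistic uses `d = night − day`
(day-dominant ⇒ t < 0) with df = n_pairs − 1, two-tailed. An inversion is a
pair with night strictly above day; ties are non-inversions. p-values are
carried at full precision and only thresholded (α = 0.05) in report
formatting; no multiplicity correction is applied, but the report counts the
tests it ran.

CV = 100·sd/mean with the n−1 sd. The 12-h day/night CVs are computed on the
phase subsets; 24-h and 48-h CVs on mass-pooled windows when raw
measurements are available, otherwise on per-window means (identical in the
µg/h regime on a uniform grid, not in the ng/mg regime).

## Rhythm detection

**ACF** uses the standard biased estimator with the full-series mean (the
convention under which the ±1.96/√n white-noise band is exact to first
order); implemented via `statsmodels.tsa.stattools.acf`. ACF and the block
ANOVA require the complete gap-free grid: a single-phase subset is
equidistant at 24 h but skips every other collection, so its lags are not
comparable to the pooled sampling step and it is rejected — whereas the
least-squares fits below accept arbitrary anchors.

**Interval ANOVA** blocks the series into consecutive groups of 8
timepoints (4 days at 12-h sampling). A trailing partial block is included
when it has ≥ 2 values (63 = 7×8 + 7 makes this consequential); a strict
mode drops it.

**Cosinor / LS spectrum.** The single-component cosinor is ordinary least
squares on `[1, cos ωt, sin ωt]`. The acrophase is the canonical angle in
(−360°, 0°] with the fitted peak at t = −φτ/360 (reference 0° = series
start); shifting the time origin by Δ hours rotates φ by +360Δ/τ and changes
nothing else. The zero-amplitude F test is exact under iid Gaussian noise;
its type-I error at n = 63 is confirmed at 0.05 by simulation in the test
suite. Designs whose condition number exceeds 1e8 (trial period resonant
with the grid — e.g. τ equal to the sampling step, or τ = 24 h on 12-h
midpoints where the cosine column vanishes identically) are rejected;
the spectrum omits such harmonics rather than aborting the scan.

Trial periods are the harmonic series τ_k = T/k of a 720-h fundamental
(30 days, the recording-length scale), k up to the Nyquist limit
τ_k ≥ 2×(sampling step). On this ladder 102.9 h and 90 h are neighbouring
harmonics (k = 7, 8). The peak band is the maximal contiguous run of
harmonics whose PR exceeds half the maximum PR; both the best-harmonic PR
and the summed band PR are reported, since a real component rarely sits
exactly on one harmonic.

## The synthetic generator

`synth.generate` integrates
`r(t) = baseline · phase_mult(t) · [1 + a_c cos(2π(t−t_peak)/24)] ·
[1 + a_s cos(2πt/τ_s + φ_s)]`
**analytically** over each window (the cross term expands into two cosines),
so pooled values carry the exact attenuation factor above; a property test
checks this to 1e-10. Noise is multiplicative mean-preserving lognormal —
concentrations stay positive and the CV is scale-free — with a *(day,
night)* CV pair, night larger, because a single CV cannot produce the higher
night-sample variability the pipeline is meant to detect. Volumes and
creatinine concentrations get their own per-phase means: day volume is
larger in proportion to day mass (so the raw concentration buries the
day–night signal) while creatinine *mass* is balanced across phases (so the
corrected series reveal it) — the mechanism by which correction uncovers a
rhythm invisible in raw concentrations. The returned truth includes the
analytically expected inversion fraction (Gaussian tail of the pair's
log-ratio).

Fixture profiles `subject1_like` (n = 63, day multiplier 1.5, 90-h fraction
0.30, noise CV 18 %/30 %) and `subject2_like` (n = 55, weaker day effect
1.15, 90-h fraction 0.18, noise CV 15 %/25 %) are frozen with fixed seeds
and shipped as CSVs; a test asserts the shipped files regenerate
bit-identically.

**What the generator does not emulate:** missing or irregular collections,
assay cross-reactivity and measurement drift, non-stationary baselines
(illness, behaviour), autocorrelated noise, or phase-jittered collection
times. Passing tests therefore demonstrate correctness of the estimators
under the stated stochastic model, not robustness to every feature of field
data.

## Calibration experiments in the test suite

* Zero-amplitude type-I error: 2000 white-Gaussian series at n = 63,
  rejection rate required within 0.05 ± 0.02 (a 10,000-simulation spot check
  gives 0.0497).
* Parameter recovery: 100 recordings at n = 63, noise CV 15 %, single 90-h
  component with amplitude fraction 0.75 and phase −80°. The amplitude
  fraction is sized a priori from the fit's phase standard error
  `(σ/A)·√(2/n)` so that the 5° phase and 10 % amplitude tolerances
  correspond to ≥ 2 standard errors; success (period within one harmonic
  step, phase ≤ 5°, attenuation-corrected amplitude ≤ 10 %) is required in
  ≥ 90 of 100 seeds (observed: 94).
* Cosinor vs brute force: the analytic fit is required to (a) never exceed
  the SSR of an exhaustive (A, φ) grid search at 0.5° / 1e-3 resolution and
  (b) agree with its argmin within resolution, on 50 random series with the
  trial period inside the series span (outside the span the SSR valley is
  flat and the grid argmin is not meaningful at any resolution).

## Numerical choices and edge cases

* Grid checks use relative tolerance 1e-9; CSV round-trips write floats at
  `repr` precision and read with pandas' round-trip parser, so
  write-then-read is bit-identical.
* Degenerate inputs raise typed errors rather than returning NaN: zero
  creatinine, constant series (ACF, CV, paired t with identical
  differences), collinear cosinor designs, windows that are not multiples
  of the sampling step.
* θ = atan2(γ, β) is wrapped to [0, 2π) with a guard that collapses values
  within 1 ulp of 2π to 0, so a noiseless peak at t = 0 reports φ = 0, not
  −360.
* All simulation sizes (2000 type-I runs, 100 recovery seeds, 500-run ACF
  band check) were chosen to bound the Monte-Carlo standard error well below
  the asserted tolerances while keeping the default suite around five
  seconds.

## Known limitations

* Single-component fits only: no simultaneous multi-harmonic cosinor or
  population-mean cosinor across subjects.
* The spectrum's harmonic ladder has coarse resolution at long periods
  (720/7 = 102.9 h vs 720/8 = 90 h); a dense period grid can be emulated by
  calling `cosinor_fit` directly over any period list.
* The ±1.96/√n ACF band ignores the lag-dependent variance correction;
  it is the conventional display band, not a simultaneous confidence set.
* The analysis assumes strict day/night alternation on an exact 12-h grid;
  recordings with missed collections must be split into gap-free segments
  upstream.
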