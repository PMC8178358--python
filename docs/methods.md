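# Methods

## Problem and pipeline

Noncontact infrared thermometers (NCITs) estimate skin-surface temperature
from emitted infrared radiance at a distance. Used for fever screening they
read far below core-temperature proxies such as a temporal-artery thermometer
(TAT), and the offset and its spread must be quantified before a screening
threshold can be chosen. The pipeline reproduces that validation logic in
order:

1. **Descriptive statistics** per measurement method (reference plus each
   NCIT distance), with t-based CIs for the mean and chi-square CIs for the
   SD.
2. **Validity gate.** A distance is excluded from method comparison when its
   readings fail normality screening (Lilliefors or Anderson–Darling at
   α = 0.05) *or* when the device's measurement spot outgrows the forehead at
   that distance (spot = distance / D:S; the target must be at least twice
   the spot). Each reason is logged separately. For a 12:1 device the spot is
   3 in at 3 ft and 6 in at 6 ft, so those distances fail the geometric check
   outright; 1 ft (1 in spot) passes.
3. **Bland–Altman agreement** on surviving distances. Differences are test
   minus reference; bias = mean(d); limits of agreement (LOA) =
   bias ± 1.96·SD(d). The LOA multiplier is fixed at 1.96 (not t-based): the
   downstream offset model defines ρ = LOA/1.96 and the two conventions must
   agree exactly. CI half-widths: t·s/√n for the bias and the classical
   large-sample t·s·√(3/n) for each limit.
4. **Offset model** ΔT ~ N(Δμ, ρ²) with Δμ = bias and ρ = SD(d). This is the
   measurement transformation used for simulation: a subject with reference
   temperature T yields a simulated NCIT reading T + ΔT.
5. **Screening accuracy.** The NCIT threshold is T*_IR = T* + Δμ + δT with
   the referent fever cut T* = 100.0 °F and δT ∈ [−LOA, +LOA]. Both the
   fever condition (ref ≥ T*) and the screen (test ≥ T*_IR) are inclusive,
   matching the "greater than or equal to" fever definition. Confusion-matrix
   rates are percentages; the ROC sweeps thresholds in 0.1 °F steps over
   [min(test)−1, max(test)+1] and integrates AUC by trapezoid over
   (FPR, sensitivity), ties broken toward higher sensitivity. The equal-error
   point interpolates linearly between the grid points bracketing
   SE − SP = 0.

All arithmetic is at full precision; rounding (half-away-from-zero, 1 dp for
temperatures, 2 dp for model parameters) happens only at display. Thresholds
are *compared* at full precision — the displayed 93.9/96.7 values are labels,
and the CLI notes when classifying at the label would differ.

## Normality tests

- **Lilliefors**: sup-distance between the empirical CDF and the normal CDF
  with mean/SD estimated from the sample. The p-value is Monte Carlo — the
  same statistic on `mc_reps` (default 5000) standard-normal samples of the
  same n, with the add-one estimator (1 + #{null ≥ obs})/(reps + 1) — so
  p-values are exact-in-distribution for the actual n and reproducible given
  the seed, rather than interpolated from lookup tables.
- **Anderson–Darling**: A² with estimated parameters, small-sample adjusted
  A*² = A²(1 + 0.75/n + 2.25/n²), p-value from the standard case-3 piecewise
  exponential approximation (D'Agostino & Stephens).
- A constant sample (SD = 0) is treated as the degenerate normal limit:
  statistic 0, p = 1, no rejection. This keeps zero-noise configurations
  runnable end to end.

Both tests hold their nominal type-I error within [α/2, 2α] at n ∈ {20, 51,
200} (checked by Monte Carlo in the suite using a shared null distribution
per n, which is statistically equivalent to per-call nulls for calibration
purposes and much faster).

## Synthetic data: what it emulates and what it does not

No subject-level data are available for either the paired study or the large
reference cohort, so both are synthesized from published summary statistics.

**Paired study** (default n = 51): reference temperatures are
normal(98.4, 0.59²) truncated to [97.1, 99.6] by rejection; each distance's
reading is reference + d with d from a skew-normal parameterized to an exact
mean (bias) and SD, then the *reading* is truncated to the published
per-distance min/max, again by rejection so the in-range shape is correct.
Defaults: 1 ft bias −6.15, SD 2.84/1.96 ≈ 1.449, bounds [88.9, 95.3], shape
0; 3 ft bias −7.1, SD 1.72, bounds [87.4, 94.2]; 6 ft bias −8.8, SD 1.68,
bounds [86.6, 92.9]; far distances use shape −20 (left-skewed: readings
degrade downward with distance).

Two honest limitations of this generator:

- Using the published min/max as hard truncation bounds shrinks the realized
  SD below the published group SD (the published values were observed
  extremes, not censoring limits). The fitted ρ on generated studies is
  therefore ≈ 1.15–1.36 rather than 1.45; analyses that need the published
  offset model take it directly (`OffsetModel()` defaults) rather than
  re-deriving it from synthetic data.
- A skew-normal difference term saturates at |skewness| ≈ 1, and truncation
  trims the skewed tail further, so the far-distance normality rejection
  rate at n = 51 is materially above α (~35–50%) but not near 1. The
  pipeline's exclusion of 3/6 ft does not depend on this: the spot-size check
  excludes them deterministically.

**Reference cohort** (default n = 578,522, TAT scale): `plain_normal` draws
from N(98.8, 0.7²) — mean 98.0 °F oral shifted by the +0.8 °F oral→TAT
adjustment; SD unchanged by the shift. Its febrile fraction beyond 100.0 °F
is the normal tail ≈ 4.32%, whereas the cohort it emulates reported 3.385%
febrile — the published distribution is evidently not normal in the tail,
and only its mean/SD/size are available. `calibrated_mixture` therefore
exists as an alternative: febrile prevalence fixed at a target, components
drawn from the same normal truncated on either side of the cut. The default
stays `plain_normal` because it adds no assumptions beyond the published
summary; simulation-based accuracy figures consequently carry tail-model
error of order 0.3–5 percentage points depending on the metric (specificity
is nearly tail-free; sensitivity and PPV are tail-dominated).

All generators are deterministic given a seed; the pipeline derives
per-stage seeds from one run seed via `numpy.random.SeedSequence.spawn`.

## Device physics

Spot geometry treats spot diameter = distance / D:S (the nominal 90%
encircled-energy interpretation), with explicit length units (1 ft = 12 in,
1 m = 39.3701 in). The forehead target extent defaults to 3 in
(configurable). Radiometry uses the Stefan–Boltzmann law M = ε·σ·T⁴ with
σ = 5.670373×10⁻⁸ W·m⁻²·K⁻⁴ and skin emissivity 0.98; an emissivity
mismatch scales apparent temperature by (ε_true/ε_assumed)^(1/4).
Accuracy/repeatability envelopes of the bundled device presets (Fluke 561,
Fluke 568, Exergen TAT-5000) are stored and reported but not simulated.

## Numerical and design choices

- Quartiles/IQR: linear interpolation between order statistics (NumPy
  default, "type 7"); published IQRs cannot distinguish conventions.
- SD is the n−1 sample estimator throughout (df = 50 for the 51-subject
  study, giving the t-multiplier 2.009).
- The lower screening threshold computes to 91.01 °F (100.0 − 6.15 − 2.84),
  which displays as 91.0; some published tables label it 91.1. The package
  reports the full-precision value and leaves the label to the caller.
- Monte-Carlo sizes in the test suite are scaled for runtime: calibration
  checks use 400–1000 replicates against a 2000-sample shared null;
  parameter recovery uses 1000 seeded replicates at n = 51; cohort-level
  checks run at the full 578,522 or at 40,000–60,000 where only rates (not
  tail counts) are asserted.

## Known limitations

- The offset model is homoscedastic and distance-specific; no
  proportional-bias (regression) Bland–Altman extension, repeated-measures
  LOA, or nonparametric LOA.
- Sensitivity-side metrics inherit the cohort tail-model error described
  above; specificity-side metrics are robust to it.
- No atmospheric-transmission or optical-PSF modelling beyond the scalar
  D:S ratio; no instrument drift or calibration simulation.
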