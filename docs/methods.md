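# Methods

This note documents the models, conventions and numerical choices behind
`spiroquant`, and what the synthetic cohort does and does not emulate.

## Template geometry

The tracing target is an Archimedean spiral r(θ) = b·θ traced outward from
the center, counterclockwise, over 4 full turns (θ_max = 8π). The only hard
physical constraint adopted is the total curve length of 56 cm; the arc
length L(θ) = (b/2)[θ√(1+θ²) + asinh θ] is linear in the pitch b, so b is
solved exactly (b ≈ 0.1761 cm/rad, outer radius ≈ 4.43 cm — a plausible
size for a printed template). Turn count and handedness are conventions:
nothing downstream depends on them beyond consistency, and both are
configurable on `SpiralTemplate`. Coordinates are cm, origin at the spiral
center, x rightward, y upward.

## Trace–template correspondence

Correspondence is by angle, not nearest point: the template is
single-valued in θ, so the drawn radius at unwrapped angle θ is compared
with b·θ. The trajectory's polar angle is unwrapped with a branch fix that
places the first retained sample at the angle implied by its radius.
Samples with radius < 0.2 cm are excluded from the polar trace because
atan2 is numerically unstable near the center and the angular assignment
there is not meaningful. Drawings must start within 2 cm of the center
(the capture protocol places the pen at the center; a start between 0.5
and 2 cm is logged, beyond 2 cm refused). If the trace locally retraces
(θ decreases), samples are kept and integration uses |dθ|, since genuinely
hypermetric drawings do backtrack.

A nearest-point correspondence was considered and rejected: it is
ill-posed where turns of a noisy trace approach each other, while the
angular map is well-defined for every sample outside the center exclusion.

## The six measures

* **Length**: chord-sum of consecutive samples. No resampling.
* **Movement time**: last minus first timestamp.
* **Average speed**: length/time — exactly consistent with the other two
  by construction.
* **Speed variability**: SD (n−1 denominator) of per-interval
  distance/time. No smoothing is applied before differencing; a smoothing
  kernel would change the measure's meaning and is deliberately not a
  default. At 60 Hz the white sensor jitter contributes a small additive
  floor, which the synthetic calibration absorbs.
* **Deviation area**: the unsigned polar area between the curves,
  ∫ ½|r_d(θ)² − r_t(θ)²| dθ, evaluated by the trapezoid rule on the sample
  grid with each interval split at sign changes of Δr (crossing angle by
  linear interpolation) so regions inside and outside the template cannot
  cancel. The integrand is exact for the annular sector between the two
  curves at a given angle; a shoelace-polygon computation on the closed
  region (out along the drawn curve, back along the template; radial
  closing edges contribute nothing) is used as an independent oracle in the
  tests, with agreement required to 0.5%.
* **Crossings**: a hysteresis counter with a ±0.02 cm deadband: a crossing
  is registered when Δr, last seen beyond one band edge, reaches beyond
  the opposite edge. The deadband suppresses double counts from sensor
  jitter (tablet noise is well below 0.02 cm per axis); at deadband 0 the
  counter reduces to a plain signed zero-crossing scan, which is the form
  verified against analytic sine zero counts. Note that a deviation zero
  whose template radius falls inside the 0.2 cm center exclusion cannot be
  observed; analytic expectations for synthetic sinusoids are only valid
  when every zero clears the exclusion radius.

## Surrogate clinical score

The visual clinical rating (ICARS spiral item with score 0 split into
0A/0B) is replaced by a fixed, monotone rule on the two accuracy measures:
0A if deviation < 4 cm² and ≤ 2 crossings; 0B if deviation < 8 cm² and
≤ 6 crossings; 1 if deviation < 16 cm²; else 2. The thresholds are
invented (a human rating has no closed form); they exist so score-level
analyses have a deterministic, testable stand-in, and they are not
calibrated to reproduce any observed score distribution.

## Synthetic cohort generator

The generator is a calibration device whose defaults are fixed to
reproduce the marginal statistics of the reference elderly population and
the trend structure the analysis stage is meant to recover. It emulates:

* **Demographics**: age ~ Normal(77.4, 6.8²) truncated to [48.7, 96.3];
  female with probability 0.606 (no-tremor) / 0.333 (tremor);
  primary-education-only 0.207 / 0.292. Strata sizes default to 1,888 and
  24.
* **Brain volumes** (mL): marginal means/SDs ICV 1462.5 ± 162.7, cerebral
  GM 454.8 ± 41.8, cerebral WM 392.7 ± 52.8, cerebellar GM 97.8 ± 10.6,
  cerebellar WM 22.0 ± 2.9; tissue volumes share a common scale with ICV
  (correlation 0.6) and decline mildly with age; white-matter-lesion
  volume is log-normal (median 6.9 mL, quartiles ≈ 3.5/14.5) with a
  positive age slope on the log scale.
* **A drawing** is the template path traversed at 60 Hz with a per-subject
  base speed (log-normal, median 3.13 cm/s at the mean age, subject log-SD
  0.47, age slope −0.010/y on the log) and i.i.d. multiplicative
  per-interval speed noise (log-SD 0.44). The radial error is a smooth
  Gaussian process in angle (squared-exponential covariance, correlation
  length 1.31 rad shrinking slightly with age) plus 0.008 cm white jitter
  per axis; the GP scale (median 0.127 cm) carries the injected covariate
  structure on its log: age slope +0.020/y, an extra quadratic term
  0.0015/y² above the knot at 75 y, −0.09 per cerebral-GM z-SD, +0.03 per
  log-WML z-SD. The radial error ramps in over the first turn so every
  drawing starts on the center. The drift scale sets the deviation area;
  the correlation length sets the crossing rate (≈ 1/(πℓ) per radian); the
  deadband makes sub-0.02 cm jitter invisible to the counter.
* **Tremor** adds a 5 Hz (configurable 4–10 Hz) radial sinusoid of 0.04 cm,
  an along-path sinusoid of 0.18 cm, and doubles the drift scale, with a
  faster base speed (median 4.40 cm/s). The along-path component is a
  deliberate modeling choice: it reverses the pen within each cycle,
  lengthening the drawing and inflating speed variability without adding
  template crossings — the combination observed in real tremor drawings,
  which a radial oscillation alone cannot produce at realistic crossing
  counts.

Calibration was done once, at the full cohort size, against the no-tremor
margins (median deviation area 5.8 cm², median speed 3.5 cm/s, mean
crossings 5.3, median time ~16 s, length ~58 cm); the defaults were then
frozen. The tremor stratum trades a slightly shorter drawn length (still
well within the observed spread) for a movement-time contrast strong
enough to be detectable at n = 24, since the group tests on all six
measures are part of the structure the generator must make recoverable.

What the generator does **not** emulate: pen pressure and lifts,
physiological tremor waveforms (amplitude/frequency drift, harmonics),
handedness effects, sex effects on performance, tablet quantization, and
any measure–covariate structure beyond the loadings listed above
(cerebellar volumes are null loadings by construction). Passing tests
therefore demonstrate that the measures and models behave correctly and
that injected effects of realistic size are recoverable — not that real
drawings follow this generative model.

## Statistical stage

* "Analysis of covariance" is ordinary least squares with the group
  indicator plus continuous/binary covariates — an equivalent
  parameterization. Sex enters as female = 1, education as
  primary-only = 1.
* Movement time, speed variability and deviation area are natural-log
  transformed before z-scoring (right-skewed); the other three are
  z-scored directly. Z-scores are relative to the analysis cohort.
* The quadratic age trend is tested as an added centered-age² term over
  the linear model; age is centered before squaring to limit collinearity.
  Continuous age is used for the trend tests; the 5-year bins (<65 …
  90+) are display-only sex-adjusted means from a bin-dummy model with sex
  mean-centered.
* Partial correlations are Pearson correlations of residuals after
  regressing each measure on age and sex.
* Brain-volume models use the volume's cohort z-score (z of the natural
  log for lesion volume), adjusting for age, sex, education and ICV z;
  cerebral volumes are additionally adjusted for total cerebellar volume
  and vice versa.
* Confidence intervals are classical t-based 95% intervals; no
  multiple-testing correction is applied; the 0.05 and 0.01 levels are
  reported, never hard-coded into decisions.
* Singular or ill-conditioned designs (condition number > 1e10) raise a
  collinearity error rather than returning unstable estimates.
* The clinical score, where analyzed numerically, is rank-coded
  0A→0, 0B→1, 1→2, 2→3.

## Numerical and validation choices

* Arc-length inversion (θ from distance along the curve) uses a 4,096-point
  cached monotone grid with linear interpolation — errors are orders of
  magnitude below the sensor noise floor.
* The GP drift is white noise smoothed by a Gaussian kernel of width
  ℓ/√2 on a 2,048-point angle grid, rescaled by the theoretical filter
  gain so the process has unit marginal variance; realized amplitude still
  fluctuates along a trace, as it should.
* Reproducibility: every stochastic entry point takes an explicit seed;
  the cohort generator spawns independent child streams per participant
  from a single `SeedSequence`, so outputs are byte-identical across runs
  and machines. The pipeline writes a manifest (config hash, seed,
  version, per-stage row counts).
* Validation strategy: closed forms (constant-offset area, alternating
  speed SD, sine zero counts), independent oracles (bisection inversion of
  arc length, shoelace polygon area, brute-force sign scan, normal-
  equations OLS), error-rate checks (ANCOVA type-I rate within
  [0.035, 0.065] at α = 0.05 over 1,000 null replicates), and parameter
  recovery (≥90% CI coverage of injected age slope, tremor shift and GM
  loading over 100 replicate cohorts at reduced n). Reduced problem sizes
  in the recovery suites (150–600 participants per replicate) keep the
  full validation run around a minute while leaving comfortable power.

## Known limitations

* The angular correspondence undercounts deviations that are locally
  tangential to the template (it measures radial error only).
* Crossing counts near the spiral center are unobservable inside the
  0.2 cm exclusion radius by construction.
* The surrogate score is not a validated clinical instrument.
* The generator's effect sizes are plausible calibrations, not estimates
  from raw data; analyses of real tablet recordings should treat the
  defaults of `GeneratorConfig` as documentation of the synthetic study
  conditions, nothing more.
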