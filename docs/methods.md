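# Methods

## The surrogate model

The heart-rate index is the ratio of an activity heart rate (submaximal
or maximal) to the resting heart rate, `HRI = HR_activity / HR_rest`.
Oxygen uptake in METs is predicted by the linear relation

    METs = 6 · HRI − 5

with the resting convention 1 MET = 3.5 mL O₂·kg⁻¹·min⁻¹. The relation
was originally fitted to aggregate data (group means from exercise-test
studies), and this package applies it the same way: the unit of analysis
throughout is the *study-level data point*, a published subgroup mean,
never an individual subject. Nothing here speaks to individual-level
predictive accuracy.

The model is defined for activity at or above rest. `mets_from_hri`
rejects indices ≤ 5/6 (nonpositive METs) rather than extrapolating, and
`heart_rate_index` rejects activity heart rates below rest; the intended
working range is HRI ∈ [1, 4], i.e. 1–19 METs. All internal arithmetic is
unrounded; print-precision rounding (METs 2 dp, heart rates and percents
1 dp, p-values 2 dp with `<0.001` below threshold) happens only at the
reporting layer, using round-half-away-from-zero because platform default
float formatting differs.

Aggregate data leave one genuine ambiguity: a pooled surrogate mean can
be formed by averaging per-point surrogate values (mean of ratios) or by
applying the index to pooled mean heart rates (ratio of means).
`compare_arm` defaults to per-point averaging, which is consistent with
treating each subgroup mean as one observation; the `pooled_hr` mode is
exposed as a sensitivity analysis and agrees with the default to within a
few percent on realistic cohorts.

## Comparison statistics

For one arm (measured or equation-predicted treadmill VO₂peak), each data
point contributes a pair (treadmill value, surrogate value from that
point's mean heart rates). The package reports:

* pooled mean ± SD per method (SD with the n−1 denominator; data points
  equally weighted by default, n-weighting available);
* the signed absolute difference and percent difference. The percent
  reference is stated per call: the surrogate when judging a treadmill
  method against it, the measured arm when comparing the two treadmill
  arms with each other;
* Student's paired t-test, two-sided, df = n−1. Zero-variance differences
  are flagged degenerate instead of raising: identical samples give
  t = 0, p = 1; a constant nonzero shift gives infinite t, p = 0;
* Bland–Altman agreement: bias = mean paired difference, 95% limits of
  agreement at bias ± 1.96 · SD of differences. 1.96 exactly, not a
  t-quantile — the convention of the clinical agreement literature;
* OLS of the treadmill values on the surrogate values, summarised as
  departure from the line of identity (slope − 1, intercept);
* a tertile report with tertiles formed on the surrogate values:
  rank-based groups of size ⌊n/3⌋, remainders allocated to the lowest
  tertiles first, ties broken by stable input order. No multiple-testing
  correction is applied across the three tertile tests.

## Treadmill prediction equations

Prediction-equation coefficients are data, not code: they live in a JSON
registry (`data/equations.json`) so the external-reference constants stay
auditable and swappable, and every report can name the equation used.
Shipped defaults: the ACSM walking triple (3.5, 0.1, 1.8) and running
triple (3.5, 0.2, 0.9) in `resting + horizontal·speed +
vertical·speed·grade` form (speed m·min⁻¹, grade a fraction ≤ 0.4), and
the Foster 1984 cubic in Bruce-protocol minutes, 14.76 − 1.379t +
0.451t² − 0.012t³, with a declared valid range of 3–21 min — the cubic is
monotone increasing on roughly 1.6–23.4 min, so the declared range keeps
predictions monotone in time. All speed/grade forms reduce to 3.5 mL
(1 MET) at zero speed, consistent with the surrogate's rest identity.
There is no automatic walk/run selection by speed: the transition is
population-dependent, so the caller chooses the form.

`handrail_adjust` divides a prediction by `1 + p/100`, the exact inverse
of a p-percent inflation; predictions from tests where support was
explicitly not permitted pass through unchanged. The operation takes the
inflation percentage explicitly (typical literature values 20–30%)
because the true inflation depends on protocol and population.

## The synthetic cohort generator

Per-point heart-rate/VO₂ values behind published pooled comparisons are
generally unavailable, so the generator emulates the assumed data
structure. For each data point i:

1. true fitness `M_i ~ Normal(mets_mean, mets_sd)`, truncated at
   ≥ 1.5 METs;
2. resting HR `~ Normal(hr_rest_mean, hr_rest_sd)`, truncated at
   ≥ 40 beats·min⁻¹;
3. `HRI_i = ((M_i + 5)/6)(1 + ε_i)`, `ε_i ~ Normal(0, hri_noise_sd)`;
   maximal HR is *derived* as `hr_rest_i · HRI_i`, so the cohort is
   consistent-by-construction with the surrogate and misspecification
   enters only through ε and the bias term;
4. the treadmill value is `M_i(1 + δ_i)` in measured cohorts and
   `M_i(1 + b_i)(1 + δ_i)` in predicted cohorts, with
   `δ_i ~ Normal(0, vo2_noise_sd)` and `b_i` either a uniform
   over-prediction fraction or a per-tertile gradient keyed by the
   true-fitness tertile;
5. the study sample size is log-uniform over 110–22,275, the range
   observed across large treadmill studies.

Default moments are the reported arm-level aggregates: measured cohorts
45 points, fitness 6.54 ± 2.28 METs, resting HR 77.6 ± 7.7, no bias;
predicted cohorts 57 points, 6.71 ± 1.92 METs, 75.6 ± 5.3, bias 0.211.
The relative noise SDs default to 0.05: no published value constrains
them, and 5% aggregate noise yields paired-difference SDs of the order
seen in study-level agreement plots while keeping the null paired-t test
well calibrated. Noise is multiplicative because reported aggregate SDs
scale with means across fitness tertiles, which additive noise would not
reproduce. HR and VO₂ errors are assumed independent: within-study
covariance between them is not published, and the assumption is stated
rather than hidden.

Randomness uses a single root seed with one `SeedSequence` substream per
variable, so identical configurations are byte-reproducible and adding a
variable never shifts existing draws. Draws violating physiology
(HRI ≤ 1, maximal HR ≥ 250, nonpositive VO₂) are redrawn from their own
substreams; the truncation points sit several SDs from the default means,
so the induced moment shift is far below Monte Carlo resolution at the
sizes used.

What the generator does **not** emulate: real between-study heterogeneity
(protocol families, diagnosis mix, age/sex structure are constants or
absent), correlation between resting HR and fitness, and within-study
HR–VO₂ error covariance. In particular the generated maximal-HR spread is
wider than reported aggregates, because maximal HR inherits the full
fitness variance by construction. Passing tests therefore demonstrate
that the *pipeline* recovers known injected structure — not that real
treadmill data satisfy the generator's assumptions.

## Validation strategy and problem sizes

Deterministic quantities (index conversions, table descriptives, group
mean arithmetic) are checked exactly. Pooled per-point results that
depend on unpublished data are replaced by property-based checks on
synthetic cohorts: recovery of an injected 21.1% bias to within 3 Monte
Carlo standard errors over 500 replicate 57-point cohorts; paired-t null
rejection rate within 0.05 ± 3·√(0.05·0.95/2000) over 2000 unbiased
45-point cohorts; noiseless regression refit returning slope 6,
intercept −5 to 1e−9; Bland–Altman bias equal to the brute-force mean
difference on 100 random cohorts; and injected tertile-gradient ordering
preserved in 100/100 gradient cohorts. These replicate counts put Monte
Carlo error well below the tested tolerances while keeping the whole
suite at a few seconds. Core statistics are additionally cross-checked
against independent routes (two-pass mean/SD loops, `scipy.stats.
ttest_rel`, normal-equations OLS, sort-based tertile assignment) on
batches of 100 random small instances.

## Known limitations

* Aggregate-only: no individual-level inference, no meta-analytic
  random-effects weighting (pooling is naive, matching the study-level
  design it reproduces).
* The descriptive fixture carries no heart-rate or VO₂ columns (never
  published per study), so the full comparison runs only on synthetic or
  user-supplied tables.
* Printed medians and demographic percentages in the source table were
  evidently computed on unpublished subgroup data points; the package
  reports the reproducible row-level quantities (e.g. measured-arm median
  337.5, n-weighted age 50.9 y) and does not force agreement with
  unreproducible prints.
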