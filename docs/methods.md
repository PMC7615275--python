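# Methods

## Setting and estimands

The package evaluates binary dementia classifiers in a symptomatic
primary-care population. Each participant carries a three-level reference
category (dementia / CIND / normal, from specialist assessment) and the
referring GP's three-level judgement. For accuracy analysis both are
dichotomized: dementia is the target condition; CIND — cognitive impairment
that falls short of dementia — counts as non-diseased, because the clinical
question is specifically the accuracy for dementia, not for any impairment.
GP judgement is likewise binarised (a "dementia" call is positive; "CIND"
and "normal" are negative).

A *strategy* is any rule mapping a participant to a positive/negative/missing
call: a single thresholded test, GP judgement alone, the AND-combination
(positive only when GP judgement and the test are both positive), or the
GP-routed sequential rule (GP-dementia patients take test A, everyone else
test B, and the routed test's call is final).

## Missing data

Missing scores are explicitly absent, never zero. Every denominator is
complete-case *per strategy*: a participant with a missing routed or
component test drops out of that strategy's table and is counted in
`n_missing`. This matters for interpretation: tests added mid-study have
smaller denominators, so AND-combined results can sit on a different
denominator than the GP-alone column, and the algebraic AND-rule bounds
(combined sensitivity ≤ each component's; combined specificity ≥ each
component's) are only guaranteed on a common complete-case subcohort. The
test suite asserts the bounds exactly in that setting.

## Interval and estimator choices

- **Binomial proportions: Clopper–Pearson.** Exact inversion of the binomial
  tails (Beta-quantile form, via `statsmodels`), two-sided, default level
  0.95. The exact method is part of the package's contract — its bounds for
  74/132 round to (47, 65) where Wilson gives (48, 64) — and the test suite
  pins it against an independent bisection of the binomial tail
  probabilities to 1e-9.
- **Likelihood ratios.** LR+ = sens/(1−spec), LR− = (1−sens)/spec, with the
  standard log-method interval; a zero denominator yields an estimate
  flagged non-finite rather than an exception.
- **AUROC.** Mann–Whitney estimator with half-credit for ties (midranks).
  The interval uses the DeLong structural-components variance, tie-adjusted,
  with a normal approximation clipped to [0, 1]; the method name is embedded
  in report metadata because other variance choices exist and give slightly
  different intervals. Each test's positivity direction orients its scores
  so larger-oriented = more disease-like; AUROC is invariant to strictly
  increasing transforms of the oriented score (property-tested).
- **Rounding.** Proportions are reported ×100, rounded half away from zero,
  at render time only; internal values are never rounded.
- **Not computable cells.** Zero denominators and single-class strata raise
  a typed error in the library and render as "." in reports.

## Natural frequencies

A strategy's confusion cells are projected onto a hypothetical population
(default 1000) from the strategy's complete-case denominator, each cell
independently rounded half away from zero. Independent rounding can make the
four cells sum to 999–1001; a largest-remainder reconciliation to an exact
sum is available and off by default, since independently rounded cells are
the convention in published natural-frequency tables.

## Bootstrap comparison

Simple case resampling: each replicate draws participants with replacement
to the original cohort size, preserving the joint distribution of reference
category, GP judgement, and all test scores; both strategies are evaluated
on the same replicate. The summary reports the mean and percentile 2.5/97.5
bounds of the per-replicate differences in FP, FN and total
misclassifications. Percentile (not BCa) intervals and 1000 replicates are
the defaults. Replicates on which a strategy has no observed calls are
recorded as missing; more than 10% missing warns. A helper ranks tests by
TP+TN within a stratum to pick comparison candidates.

## Durations and throughput

Durations are minutes as decimals. The summary statistic is the 95th centile
(C95) by the **nearest-rank** method (sorted element ⌈0.95 n⌉): reported
durations are whole minutes, so interpolation choices are immaterial at that
rounding, and nearest-rank is fixed for determinism. Tests are binned by
C95: short < 5 min, medium 5–10 min inclusive, long > 10 min.

The throughput model assumes a clinician spends 37.5 h/week (2250 min)
purely administering tests — a deliberate simplification that bounds weekly
capacity at `minutes_per_week / C95`. C95 and accuracy are both stratified
by GP judgement (tests take longer in people GPs suspect of dementia), and
the stratified C95s are averaged over the cohort's GP-judgement mix
(86/240 vs 154/240 under the default spec) before dividing; the exact
weighting is a design choice recorded in report metadata. The capacity is
capped at a population of 1000, with the cap applied to the total assessed.
Expected TP/FP/TN/FN follow by total probability from each stratum's
sensitivity, specificity and prevalence applied to the assessed mix, and sum
to the number assessed. Informant questionnaires are costed at the minimum
C95 among cognitive tests, since the informant completes them while the
clinician evaluates the patient.

Indirect standardization of the potentially eligible population is the plain
sum over age bands of list size × external age-specific incidence ×
person-time; the published eligible-count figure needs external list-size
and incidence inputs that are not distributed here, so the operation is
provided but no reference value is asserted.

## Synthetic cohort generator

The generator's defaults encode the study conditions: n = 240; reference
prevalences 132/61/47 of 240; GP judgement drawn from the published
reference-conditional 3×3 rows (e.g. P(GP dementia | dementia) = 74/132, so
the implied GP sensitivity is 56.06%). Six index tests span the three
families (MoCA, 6CIT, SPMT, Eurotest cognitive; IQCODE informant; TUG
physical), each with a per-category Gaussian score model. Means are derived
by inverting the Gaussian tail at the test's threshold so that the implied
operating point lands at a published-range value, with CIND intermediate
between dementia and normal (the three-component mixture reflects the graded
severity the study observed). The true per-test score distributions were
never published, so these models are illustrative: parameter-recovery tests
show the pipeline recovers whatever operating points the generator encodes,
not that the generator matches real score data.

Durations are log-normal (nonnegative, right-skewed, as the published ranges
suggest) with dementia medians above normal medians. Missingness is per
test: a leading fraction of the cohort in recruitment order (the mid-study
addition pattern, 20% for the MoCA-like test) plus an optional
missing-completely-at-random rate.

`implied_operating_point` returns the analytic (sensitivity, specificity) of
any test under a spec — dementia tail probability at the threshold, and the
CIND/normal tails mixed by their prevalence within non-disease — and is the
oracle for recovery tests (checked against numeric quadrature).

What the generator does **not** emulate: inter-test correlation beyond the
shared latent category (unreported in the source setting), item-level test
structure, spectrum effects within categories, and informative missingness.
Consequently, synthetic stratified-vs-unstratified bootstrap comparisons are
demonstrations of the machinery, not reproductions of any published
exploratory result; and published individual-level quantities (combined-test
columns, stratified AUROC/PPV/NPV tables, per-test natural frequencies)
cannot be reproduced without the original data. Those surfaces are covered
by exact algebraic bounds, independent-oracle equivalence, and qualitative
prevalence-driven orderings (PPV higher / NPV lower in the GP-dementia
stratum) instead.

## Problem sizes used in validation

Parameter recovery uses 50,000-participant cohorts (Monte-Carlo SE of a
proportion ≈ 0.3%, so a 3-SE band is ±1%); AND-rule bounds are checked on
1000 generated cohorts of n = 240; AUROC is checked against pairwise
enumeration on 500 random instances of n ≤ 30; bootstrap calibration uses
2000 replicates against a closed-form expectation with a variance that is
analytic because distinct tests are conditionally independent given the
reference category. These sizes make every check tight while keeping the
full suite fast.

## Determinism

All randomness flows through `numpy.random.default_rng` seeds carried in
specs and function arguments; reruns with equal inputs and seeds produce
byte-identical report bundles (metadata embeds the seed, interval methods,
rounding rule, and per-test complete-case denominators — never timestamps).
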