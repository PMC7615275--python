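# briefcog

Diagnostic accuracy of brief cognitive tests for dementia in primary care,
evaluated alone and together with the referring GP's clinical judgement.

When a patient over 70 consults their GP with cognitive symptoms, the GP can
reach for any of a dozen brief cognitive assessments (MoCA, 6CIT, SPMT,
Eurotest, IQCODE, ...), each with a prespecified threshold, or rely on
clinical gut feeling — recorded here as a three-level judgement (normal /
cognitive impairment not dementia (CIND) / dementia). `briefcog` implements
the statistical machinery for comparing these options against a specialist
reference standard in which dementia is the target condition and CIND is
grouped with normal:

- **2×2 accuracy with exact intervals.** Sensitivity, specificity, predictive
  values and likelihood ratios from confusion tables, each binomial
  proportion with a Clopper–Pearson interval (inversion of the binomial tail
  probabilities, so a table x/n gets bounds from the Beta quantiles
  B(α/2; x, n−x+1) and B(1−α/2; x+1, n−x)).
- **Combination and stratification by GP judgement.** The AND-rule (positive
  only when GP judgement *and* test are positive), accuracy restricted within
  the GP-dementia / GP-not-dementia strata, GP-routed sequential strategies
  (`seq:TEST_A/TEST_B` — judge-dementia patients get test A, the rest test B),
  and AUROC (Mann–Whitney with half-credit for ties, DeLong intervals) per
  stratum.
- **Natural frequencies.** Any strategy's confusion cells projected onto a
  hypothetical population of 1000 people, the standard risk-communication
  format.
- **Bootstrap strategy comparison.** Case-resampled differences in false
  positives / false negatives / total misclassifications between two
  strategies, with percentile intervals.
- **Clinician throughput.** How many people a full-time clinician
  (37.5 h/week of test administration) could classify per week, from
  GP-stratified accuracy and the 95th-centile test duration (C95), with
  informant questionnaires costed at the fastest cognitive test's C95
  because the informant answers while the clinician assesses the patient.
- **Synthetic cohorts.** Individual-level data for such studies are rarely
  distributable, so a generator reproduces the study structure — reference
  prevalences 132/61/47 of 240, GP judgement drawn from the published
  reference-conditional 3×3, Gaussian category-conditional scores with known
  analytic operating points, log-normal durations, per-test missingness —
  making every pipeline stage testable end to end.

## Worked example

Quantities that depend only on GP judgement and the reference standard can be
computed from the published 3×3 cross-tabulation, expanded to an
individual-level cohort:

```python
from briefcog import (study_crosstab_cohort, Strategy, StrategyKind,
                      evaluate_strategy, sensitivity, specificity,
                      strategy_natural_frequencies)

cohort = study_crosstab_cohort()                      # 240 participants
gp = Strategy(StrategyKind.GP_ALONE)
ct = evaluate_strategy(cohort, gp)
print(ct)                                             # tp=74 fp=12 fn=58 tn=96
print(sensitivity(ct).as_percent())                   # (56, 47, 65)
print(specificity(ct).as_percent())                   # (89, 81, 94)
print(strategy_natural_frequencies(cohort, gp))
# population=1000 tp=308 fp=50 tn=400 fn=242
```

GP judgement alone is insensitive (56%, 95% CI 47–65%) but specific (89%,
81–94%): in 1000 such patients, GPs would call 358 demented and be right
about 308 of them, while 242 people with dementia would be missed.

The full pipeline runs on any cohort CSV or a synthetic one:

```python
from briefcog import default_study_spec, generate_cohort, run_pipeline

cohort = generate_cohort(default_study_spec(n=240), seed=7)
bundle = run_pipeline(cohort, seed=7)
print(bundle.accuracy.head(4).to_string(index=False))
```

```
        test   n     sensitivity   specificity  combined_n combined_sensitivity combined_specificity
GP Judgement 240   51 (42 to 60) 91 (84 to 95)         240                    .                    .
        MoCA 192 100 (96 to 100)  14 (8 to 23)         192        47 (37 to 58)        92 (84 to 96)
        6CIT 240   83 (75 to 89) 75 (66 to 83)         240        41 (32 to 50)        97 (91 to 99)
        SPMT 240   75 (66 to 82) 81 (73 to 88)         240        40 (31 to 49)       99 (95 to 100)
```

Note the pattern the AND-rule forces: combining each test with GP judgement
trades sensitivity for specificity. MoCA's n is 192 because the generator
emulates its mid-study addition (the leading 20% of the cohort lack it), so
its denominators are complete-case.

The same bundle carries stratified accuracy, natural frequencies, duration
summaries and throughput; or use the CLI:

```sh
briefcog simulate --n 240 --seed 7 --out cohort.csv --tests-out tests.json
briefcog accuracy cohort.csv tests.json
briefcog bootstrap cohort.csv tests.json --a SPMT --b seq:IQCODE/6CIT --reps 1000 --seed 7
briefcog report cohort.csv tests.json --out report/
```

The default test definitions (thresholds, positivity directions) are
illustrative configuration, not code: supply your own JSON to evaluate other
instruments or cut-points.

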