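# bloodclock

Aging clocks are regressors trained to predict chronological age from
physiological measurements; an individual's prediction is read as their
*biological age*, and the signed prediction error as *age acceleration* —
a proxy for how fast they are aging. `bloodclock` implements a complete
three-stage analysis of this kind for blood-panel/biometric cohorts of
older adults (modelled on the structure of the China Health and
Retirement Longitudinal Study), for biostatisticians and epidemiologists
who want the full chain testable end to end:

1. **Clock** — a feed-forward network (5×256, ELU, dropout 0.35, L2 1e-5)
   regressing chronological age on 24 predictors (16 blood panel
   variables, sex, fasting flag, 6 biometric variables), trained with an
   MAE objective and 5-fold cross-validation, with min-max feature
   scaling, mean-age and elastic-net baselines, and permutation feature
   importance. Metrics are MAE (years), MAPE (percent) and R² computed
   with population variance, `R² = 1 − Σe²/(N·Var(age))`.
2. **Disease association** — for each serious condition, participants
   with the *isolated* condition are compared to healthy controls matched
   by nearest-neighbour search on normalized (age, sex, living area),
   sampled with replacement; the effect is `delta = mean afflicted error −
   mean control error` (years), tested with a two-sided Mann-Whitney U.
3. **Attribution** — biological age is regressed (elastic net, 10-fold CV
   over alpha ∈ {1e-5 … 100} × l1_ratio ∈ {0.00 … 0.99}) on chronological
   age plus 13 binary indicators (sex, marital status, rural living,
   smoking, eight "rarely …" psychological indicators); every coefficient
   reads directly as years of age acceleration, with σ over ten seeded
   re-splits, and the aggregate psychological effect is Σ|β| over the
   eight psychological indicators.

Because the cohorts such analyses run on are typically restricted-access,
the package ships a first-class **synthetic cohort generator** with a
known latent aging-pace model: every participant's predictors are
generated at their *effective age* (chronological age plus injected
disease/lifestyle/psychosocial effects plus residual pace), so every
stage can be validated against exact ground truth. See `docs/methods.md`
for the model details, calibration rationale, and what synthetic results
do and do not demonstrate.

## Worked example

```python
import numpy as np
from bloodclock import (SyntheticConfig, generate_cohort, exclude_invalid,
                        assign_sets, train_clock, predict_age,
                        compute_metrics, mean_age_baseline)

cohort, truth = generate_cohort(SyntheticConfig(n_participants=4000, seed=7))
clean, _ = exclude_invalid(cohort)
splits = assign_sets(clean, seed=8)
train, test = splits.subset(clean, "train"), splits.subset(clean, "test")
model, cv_records = train_clock(train, seed=9)
print(compute_metrics(cv_records))
records = predict_age(model, test)
print(compute_metrics(records))
```

prints (from `python examples/02_train_clock.py`, which adds baselines
and feature importance):

```
train 1754, test 1557 participants
clock   CV: MAE 1.80 y, MAPE 2.76 %, R2 0.970
clock test: MAE 1.83 y, R2 0.969
mean-age test MAE 11.26 y  (the clock should be far below this)

top-5 features by permutation importance (ΔMAE, years):
           feature  delta_mae  delta_mae_sd
               bmi   0.918725      0.026944
        hemoglobin   0.742974      0.010662
c_reactive_protein   0.496463      0.012410
             hba1c   0.481123      0.002405
    platelet_count   0.474663      0.015433
```

The CV MAE of ≈1.9 years sits just above the generator's irreducible
error (≈1.3 y posterior SD at this cohort size), and the mean-age
baseline is an order of magnitude worse — the clock has learned the age
signal. Downstream, `examples/03_disease_association.py` recovers the
injected disease deltas (e.g. +2.2 y for lung disease) in matched
cohorts, and `examples/04_psychosocial_attribution.py` recovers the
injected attribution coefficients (smoking +1.25 y, married −0.59 y, …)
and the ≈1.6-year aggregate psychological effect.

The `examples/` directory has one short script per capability; the
`bloodclock` CLI (`simulate`, `clock`, `associate`, `attribute`,
`run-all`, `validate-config`) runs the same pipeline from a YAML config
(`examples/pipeline.yaml`) and writes diffable TSV/JSON reports with
provenance headers and a seed log. Reruns at the same master seed are
byte-identical.

## Numeric-determinism caveats

Results are deterministic given the master seed on a fixed platform.
Across BLAS implementations or CPU architectures, float32 matmul
reduction order may differ, which can shift network weights and hence
third-decimal metric values; the statistical conclusions of the studies
are insensitive to this.
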