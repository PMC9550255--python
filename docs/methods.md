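# Methods

`bloodclock` implements a three-stage epidemiological analysis — an aging
clock, matched-cohort disease comparison, and psychosocial attribution —
together with the synthetic cohort generator that makes the whole chain
testable against known ground truth. This note records the models, the
parameters that matter, the numerical choices, and the limits of what the
synthetic results demonstrate.

## The aging clock

The clock is a regressor of chronological age on 24 predictors: 16 blood
panel variables (total cholesterol, LDL, HDL, C-reactive protein, glucose,
triglycerides, uric acid, cystatin C, MCV, creatinine, HbA1c, hemoglobin,
hematocrit, BUN, platelet count, WBC count), sex, a fasting indicator, and
6 biometric variables (systolic and diastolic pressure, BMI, waist
circumference, heart rate, spirometry). Its prediction for a participant
is their *biological age*; the signed prediction error

    acceleration_i = Age_predicted,i − Age_true,i

is the age-acceleration estimate used by both downstream stages.

The model is a feed-forward network — five hidden layers of 256 units,
ELU activations, dropout 0.35 and L2 weight decay 1e-5 after each hidden
layer, a linear output — trained by minimizing mean absolute error.
Features are min-max scaled to [0, 1] on the training set; values outside
the training range extrapolate linearly and are deliberately not clipped
(clipping would flatten the oldest/youngest extremes). A constant training
feature is mapped to 0 with a warning. The implementation is a compact
numpy MLP (`bloodclock.nn`): minibatch Adam (learning rate 1.5e-3, batch
128), at most 500 epochs, early stopping when the MAE on a 10% validation
split stops improving for 20 epochs, best-validation weights restored.
Batch 128 rather than a smaller batch is an engineering choice: on a
single CPU with BLAS matmuls it roughly halves wall-clock at equal final
error. Everything is float32 and deterministic given the seed.

Training uses 5-fold cross-validation: each fold's model predicts its
held-out fold (these out-of-fold records give the CV metrics), then a
final model is refit on all training rows and is the one used for every
downstream biological-age prediction. Metrics follow the population-
variance convention:

    MAE  = (1/N) Σ |Age_true − Age_pred|            [years]
    MAPE = (100/N) Σ |Age_true − Age_pred|/Age_true [percent]
    R²   = 1 − Σ error² / (N · Var(Age_true))

so a constant prediction at the mean of the truths scores R² = 0 exactly.
Baselines: mean-age assignment, and an elastic net on the same scaled
features with hyperparameters chosen by cross-validated grid search over
alpha ∈ {1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 0, 1, 10, 100} and l1_ratio ∈
{0.00, 0.01, …, 0.99}, scored by MAE (alpha = 0 is fitted as ordinary
least squares). Permutation feature importance is the mean change in MAE
when one feature column is shuffled (seeded, averaged over repeats).

## Cohort hygiene and the set partition

Cohorts are plain CSVs validated against a variable schema
(`data/schema.yaml`) that carries units, broad physiological plausibility
ranges, categorical levels and the covariate→indicator mapping. The
exclusion stage removes rows with missing sex, a missing predictor, a
predictor outside its schema range, or (fallback screen) a within-column
|z| > 5; each exclusion is logged with its rule. Repeated biometric
readings (`systolic_bp__1`, `systolic_bp__2`, …) are averaged over
non-missing repeats before validation.

The partition mirrors the reference design: any history of a serious
condition (cancer, heart disease, stroke, lung disease, liver disease)
routes a participant to the *discovery* set; the milder tracked
conditions (hypertension, arthritis, dyslipidemia, kidney disease,
diabetes) go to the *test* set; fully healthy participants are split
between train and test by a seeded draw. The healthy-train fraction
defaults to 0.66, which at default prevalences reproduces the reference
≈52/48 train/test balance.

## Matched-cohort disease comparison

For each serious condition, the afflicted sample is restricted to
*isolated* cases (no other tracked condition). Controls are drawn from
the healthy test pool by nearest-neighbour search on (age, sex, living
area), min-max normalized jointly over afflicted ∪ pool, sampled with
replacement, one control per afflicted participant. Binary coordinates
cost their full normalized scale, so categorical mismatches only occur
when exact matches are exhausted; ties resolve to the pool row appearing
first after a seeded shuffle. The test statistic is the two-sided
Mann-Whitney U on the clock errors — exact enumeration when both samples
are ≤ 20 and untied, the tie-corrected normal approximation otherwise —
and the effect estimate is delta = mean afflicted error − mean control
error, in years. No multiple-testing correction is applied across
conditions (mirroring the reference analysis); the report flags p < 0.05.

A caveat established while calibrating the type-I simulation: when the
control pool is small relative to the afflicted sample, with-replacement
matching reuses controls and the resulting dependence inflates the U
test's rejection rate (measured ≈0.066 at pool 400 vs ≈0.056 at pool
1000 for 60 afflicted). Keep the healthy pool an order of magnitude
larger than the afflicted group.

## Psychosocial attribution

Biological age is regressed, with an elastic net over the same
hyperparameter grid (10-fold CV, MAE-scored), on chronological age
(unscaled, so its coefficient is years-per-year) plus 13 binary
indicators: is_male, is_married, is_widowed (never-married is the
reference level with both zero), is_rural, currently_smoking, and eight
"rarely …" psychological indicators. Each psychological indicator is 1
iff the corresponding CES-D-style frequency item is at its lowest level
(< 1 day in the past week) — for positively worded items (hopeful, happy)
"rarely" likewise means the lowest frequency of the feeling. The clock's
blood/biometric inputs are deliberately excluded from the design: they
are implicitly present in the target.

The design pools the clock's train and test participants and re-splits
them 70/30. Hyperparameters are selected once, by grid search on the
primary split; ten seeded iterations then redo the re-split and refit at
those hyperparameters. The reported coefficient is the mean over the ten
refits and σ its standard deviation — σ therefore measures subsampling
stability at fixed hyperparameters, not hyperparameter-selection
variability. The report flags |β| > 2σ without claiming that this equals
any particular significance criterion. The aggregate psychological effect
is Σ|β| over the eight psychological indicators: the spread, in years,
between the most and least favourable configuration of each indicator.

## The synthetic cohort generator

The generator is the testbed that closes the loop. Each participant draws
a chronological age (uniform on [45, 90] by default — the cohort design
targets adults over 45), sex, fasting status, living area, marital
status, smoking, eight 4-level psychological frequency items, and ten
independent disease flags. A latent *effective age* is then

    effective_age = chronological_age
                    + Σ disease effects over active flags
                    + Σ covariate effects over active indicators
                    + residual pace draw (Normal, SD 1.5 y),

and every continuous predictor is generated *at the effective age* from
an affine-in-age curve (optional quadratic term) with a sex offset and
Gaussian noise. This makes the injected effects exactly the quantity a
perfect pipeline would recover, and the bookkeeping identity above is
checkable to machine precision from the truth sidecar.

Default effect sizes replicate the reference attribution coefficients
(smoking +1.25 y, married −0.59 y, widowed +0.27 y, rural +0.39 y, the
eight psychological indicators between −0.44 and +0.35 y) and the
reference disease deltas (lung +2.2 y, stroke +1.49 y, liver +0.97 y,
heart −0.03 y, cancer −1.07 y; the five milder conditions 0). Default
prevalences are sized to the reference per-condition counts in an
11,914-participant cohort, which is also the default cohort size
(≈5,200 train rows after partitioning).

Two deliberate simplifications:

* **Noise is calibrated for recoverability, not realism.** Per-biomarker
  noise SD is 0.6× the magnitude of the per-decade slope, so the 22
  continuous predictors jointly determine age with an irreducible
  posterior SD of ≈1.3 years (clock MAE ≈1.6 y). The calibration target
  is that 0.05–1.25-year injected effects be recoverable with a margin of
  at least ~3 standard errors at cohort size 10⁴, net of the structural
  attenuation terms (elastic-net shrinkage at the CV-selected penalty,
  the clock's implicit subtraction of the acceleration expected given the
  biomarkers, and edge compression near the age boundaries). Real blood
  panels carry far less age information (reference clock MAE 5.68 y);
  passing recovery tests here therefore demonstrates correctness of the
  pipeline's machinery, not attainable precision on real data, where
  coefficient attenuation of order 10–20% should be expected.
* **Diseases and covariates act only through the shared effective-age
  shift** — no condition-specific biomarker signatures — keeping the
  ground truth one-dimensional and recovery tests unambiguous.

The fasting flag is generated but carries no signal, providing a built-in
negative control for permutation importance.

### A structural identifiability limit: the sex coefficient

The injected male effect (+0.42 y) is *not* recoverable by the
attribution stage, and this is a property of the design, not a bug: sex
is one of the clock's 24 inputs, so a clock trained to predict
chronological age calibrates each sex's predictions to that sex's
chronological ages — any sex-constant acceleration is absorbed into the
clock's sex-conditional baseline and never reaches the biological-age
target (measured is_male coefficients on synthetic data sit near 0.07
rather than 0.42). The same argument applies to any binary factor the
clock sees as a feature; smoking and the psychological indicators are
recoverable precisely because the clock does not observe them. One
corollary worth noting: a *real* clock's male coefficient in such an
attribution partly reflects imperfect sex calibration of the clock rather
than pass-through of genuine acceleration. The acceptance suite keeps one
deliberately failing test documenting this limit.

## Reproducibility and problem sizes

A single master seed fans out to per-stage seeds through
`numpy.random.SeedSequence` (all derived seeds logged); pipeline runs are
byte-identical across reruns at the same seed, and all randomness flows
through explicitly passed generators. The canned studies
(`bloodclock.studies`) use the default cohort (11,914 participants) for
clock sanity, 10,000 participants for attribution recovery, and 1,000
simulated pairs plus one ≈500-afflicted end-to-end run for the matched
comparison — sizes chosen to keep each study within a few minutes on one
CPU while leaving the recovery margins described above.

## Known limitations

* The generator has no missing-data mechanisms beyond optional
  missing-sex injection, no survey weights, no longitudinal waves, and no
  correlation between covariates (smoking is independent of sex, unlike
  in real cohorts).
* The exclusion z-screen uses moment-based z-scores; it is idempotent in
  practice on realistic data but not by construction for adversarial
  inputs.
* Elastic-net σ is subsampling variability at fixed hyperparameters;
  hyperparameter-selection uncertainty is not propagated.
* Disease flags are drawn independently, so "isolated condition"
  subsamples are larger than they would be in a comorbidity-correlated
  population.
* The generative biomarker curves are nearly affine in age (only three
  carry small quadratic terms), so the elastic-net baseline is
  competitive with the network on synthetic cohorts; the network's
  advantage on real data comes from nonlinearity the generator does not
  attempt to model. Synthetic runs test the machinery, not the relative
  ranking of the two model families.
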