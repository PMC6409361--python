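# Methods

`absig` models the dichotomised status of cerebrospinal-fluid (CSF)
amyloid-beta 1-42 — abnormal when the level falls strictly below the
clinical threshold of 192 pg/ml — from blood measurements: plasma protein
analytes, serum metabolites, age and APOEε4 carrier status. Because the
clinical cohorts that motivate this design are access-restricted, the
package ships a calibrated synthetic cohort generator and evaluates the
full analysis pipeline on data with known ground truth.

## Synthetic cohort generator

Each subject draws independent analyte levels (normal, mean 100, SD 15).
A small set of *informative* analytes, plus APOEε4 carrier status,
contribute additively to a latent CSF level:

```
latent = csf_mean + apoe4_effect * carrier + sum_j sign_j * size_j * z_j
level  = latent + Normal(0, csf_sd)
```

where `z_j` is the standardised informative analyte. True amyloid status
is `level < 192`. The defaults were calibrated once, by Monte Carlo,
so that:

- abnormal prevalence in the CSF arm is ≈ 0.67, matching the case mix of
  elderly memory-clinic cohorts enriched for amyloid pathology;
- the oracle linear score separates statuses with AUC ≈ 0.85, the level
  of blood-based discriminability reported for panels of this kind.

The default informative analytes are named for the four plasma markers
most consistently associated with CSF amyloid — chromogranin A (`CGA`,
+14 pg/ml per SD), plasma Aβ1-42 (`AB42`, +12), apolipoprotein E
(`APOE`, +10) and eotaxin-3 (`Eotaxin3`, −12) — with the APOEε4 carrier
effect at −28 pg/ml and residual noise SD 27. The closed-form
discriminability of any single additive effect is
`binormal_auc(delta, sigma) = Phi(delta / sqrt(2 sigma^2))`, which the
test suite uses as an oracle.

The default cohort has 566 subjects: 356 with a measured CSF level (the
training arm) and 210 without (the validation arm, all with mild
cognitive impairment, MCI). Panels default to 149 proteins and 138
metabolites. Diagnosis mix is conditional on true status —
P(CN, MCI, AD | normal) = (0.50, 0.45, 0.05) and
P(CN, MCI, AD | abnormal) = (0.00, 0.61, 0.39). A fraction (0.31) of
subjects carry 1–2 amyloid-PET scans whose status agrees with the true
CSF status except for a Bernoulli(7/108) discordance flip; SUVR values
are drawn within a half-unit band on the matching side of the tracer
threshold (PiB 1.5, AV45 1.11; abnormal iff SUVR ≥ threshold, earliest
scan per subject, PiB preferred on same-day ties). Conversion from MCI
to Alzheimer's dementia follows an exponential hazard of 0.003/month for
CSF-normal subjects with a hazard ratio of 3.0 for abnormal, censored
administratively at 120 months; subjects already demented at baseline
convert at time zero. Analyte cells are blanked completely at random at
rate 0.02 by default.

All randomness derives from a single root seed through SHA-256-based
stream derivation (`absig._seeds.derive_seed`), so every stage is
independently and platform-stably seeded.

## Quality control and imputation

Analytes missing in strictly more than 15% of subjects are dropped;
subjects missing strictly more than 5% of the surviving analytes are
flagged. Remaining gaps are filled by iterative chained regression
forests in the style of missForest: initialise missing cells with column
medians, visit columns in order of increasing missingness, regress each
on all others over its observed rows (100 trees), and stop at the first
increase of the summed squared change of the imputed cells, returning
the previous sweep. Observed cells are never altered.

## Random-forest models

Forests use 2000 trees by default with `mtry = floor(p^0.75)` candidate
features per split and the reference forest implementation's default
terminal node sizes (5 observations for regression, 1 for
classification); tree induction is delegated to scikit-learn's CART
forests. Two task modes exist: *regression* on the continuous CSF level
(later dichotomised by a data-driven cutoff) and *binary* on the status
directly.

Out-of-bag (OOB) bookkeeping is computed in-package by replaying each
tree's bootstrap sample from its stored random state: per-row OOB
predictions, OOB error, and Breiman-style OOB permutation importance
(mean increase in a tree's OOB error when one feature's OOB values are
shuffled; features a tree never splits on contribute exactly zero).
The replay is verified against the backend's own OOB predictions in the
test suite.

## Cutoff derivation

Regression predictions are dichotomised by a threshold chosen on
*training* data only, from the forest's OOB predictions, among six
published criteria: Youden's J, the point closest to (0,1) on the ROC
(ROC01), maximum of min(Se, Sp), maximum Se·Sp product, maximum
efficiency (accuracy), and maximum kappa. Candidate thresholds are the
midpoints between adjacent distinct predicted levels plus sentinels
beyond the observed range; exact ties are broken toward the candidate
closest to the median predicted level. Orientation is fixed: predicted
level strictly below the threshold means abnormal.

## Nested cross-validation

Performance is estimated with repeated nested cross-validation —
by default 10 repetitions of 10 outer folds, stratified by CSF status.
Within each outer training set, a 3×3 inner cross-validation picks the
cutoff criterion with the highest mean inner-test accuracy; the forest
is then refitted on the full outer training set, the cutoff derived from
its OOB predictions under the chosen criterion, and AUC, accuracy,
sensitivity, specificity and R² computed on the untouched outer test
fold. Models (feature sets B = age + APOEε4, BP = B + proteins, BM = B +
metabolites, BPM = all) are compared on their paired per-fold AUCs with
a one-tailed Wilcoxon signed-rank test — exact by convolution over
midranks up to n = 25, normal approximation with tie correction beyond —
at a Bonferroni-adjusted level (divisor 5).

## Feature selection

Backward elimination ranks features by OOB permutation importance,
drops the bottom 20% per step while more than 30 remain, then one at a
time, re-ranking after every refit. The subset size is the smallest
whose inner-CV AUC is within 4% of the path maximum (read relatively,
`auc ≥ 0.96 · max`; an absolute reading is available). The production
subset is obtained by re-running the elimination on the full training
cohort down to the selected size.

## Clinical validation

On the validation arm (MCI subjects without CSF), the fitted model's
predicted status stratifies time-to-conversion. Kaplan-Meier curves use
Greenwood log(−log) confidence bands; strata are compared with the
log-rank test and a Cox proportional-hazards hazard ratio (single binary
covariate, Breslow tie handling, Newton-Raphson, Wald 95% CI). Log-rank
tests additionally compare each predicted stratum with the corresponding
measured-status stratum of the training arm (cross-cohort equivalence).
PET concordance is the AUC of the model's abnormality score against
PET-derived status on subjects with a scan.

## Problem sizes in the test suite

The full design (2000 trees, 10×10 outer CV, 566 subjects, 287 analytes)
is a multi-hour single-CPU computation. The test suite exercises the
identical code paths at reduced sizes chosen from runtime profiling:
200-tree forests for feature-selection recovery (n = 400), 100–150-tree
forests and 1–2 repetitions of 3–5 outer folds for cross-validation
properties, and scaled-down cohorts elsewhere. Statistical assertions
use tolerances derived from the sampling distributions at those sizes.

## Limitations

- Analytes are generated independently except through the latent level;
  real panels have correlated blocks beyond this.
- Missingness is MCAR; the QC thresholds are calibrated for that regime.
- The Cox model covers the single-binary-covariate case used in the
  validation analysis, not general covariate matrices.
- The binary task reports the OOB abnormal-vote fraction as its score;
  probability calibration is out of scope.
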