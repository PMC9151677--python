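# Methods

`craftct` re-creates, on fully synthetic data, the workflow by which
CT-based equations for daily creatinine excretion are developed and
validated.  Because the clinical datasets behind such equations are not
shareable, every stage here runs against a simulation with a known ground
truth, so the statistical machinery — selection rules, imputation,
consensus variable selection, pooled confidence intervals — can be tested
for *recovery of truth* rather than against fixed printed numbers.

## The estimand and the study design being emulated

24-h urinary creatinine excretion (mmol/day) is, at steady state, a proxy
for daily creatinine production, which is driven largely by muscle mass.
The emulated design: adult patients with an abdominal CT scan and a 24-h
urine collection within two weeks of the scan, split 60/40 by subject into
development and validation sets, plus a separate cohort of healthy kidney
donors with 2–3 consecutive collections.  Two linear equations are
developed, one over the full clinical + body-composition pool ("CRAFT 1")
and one excluding weight and stature ("CRAFT 2"), and both are compared
with the Cockcroft–Gault and Ix demographic formulas.

## Synthetic cohort

A single latent Gaussian "muscle mass" factor rises with male sex and
weight and falls with age.  Compartment cross-sectional areas at L3
(psoas, long spine, abdominal wall, subcutaneous and visceral fat) and
mean attenuations are affine in this factor plus noise; attenuation also
declines with age.  The remaining first-order radiomics columns
(percentiles, SD, min/max, skewness, kurtosis) are derived from each
compartment's mean and a per-subject dispersion, giving realistically
correlated nuisance predictors.  The correlation structure among radiomics
columns is a modelling choice (no published covariance exists); its noise
scale is exposed in the config.

True production is a sparse linear equation over features; observed
excretion adds Gaussian collection noise and is floored at 0.5 mmol/day so
percentage errors stay defined.  A calibration routine
(`calibrate_truth`) rescales a chosen coefficient direction against a
large probe sample so that the marginal excretion distribution and the
truth R² hit their targets.  Defaults target the published cohort's
characteristics: ~49% female, age 55 ± 14 y, weight 78 ± 18 kg, stature
173 ± 10 cm, excretion ~12 ± 4.1 mmol/day with the truth explaining ~60%
of variance, compartment areas/attenuations of roughly 19/44/68 cm² and
44/38/34 HU, weight missing in ~22% and stature in ~9% of patients
(< 1% in donors).

Missingness is MAR, logistic in care setting and age (inpatients and
older subjects lose their weight record more often); the intercept is
solved numerically so the realised marginal rate matches the target.
Plasma-creatinine series are near-constant for steady subjects; a
configurable fraction drifts linearly with a slope scaled to the subject's
weight so the implied daily change in total body creatinine exceeds the
exclusion limit.  Donor collections are drawn around the true excretion
with spread `intraindividual_sd / c4(k)`, where `c4(k)` is the normal
small-sample bias factor of the SD — the reported statistic is the *mean
of per-donor sample SDs* over k = 2–3 collections, and without this
correction the generator would systematically undershoot the configured
value (1.47 mmol/day) by 10–20%.

All randomness derives from one master seed through fixed per-stage
substreams, so cohorts are bit-identical across reruns.

## Phantoms and feature extraction

The pretrained networks that localise L3 and segment compartments on real
scans are prior work and are not re-implemented; their *output* is
replaced by geometric ground truth.  A phantom is five contiguous 5-mm
slices (a 2.5-cm range) of disjoint compartment ellipses on an air
background, with HU drawn per compartment from truncated normals.  Ellipse
semi-axes are derived from target areas at fixed aspect ratios and laid
out in two rows with guaranteed gaps, so per-subject phantoms stay
disjoint for any realistic body composition.  Rasterisation is
pixel-center-in-ellipse, which converges to the analytic area πab as the
grid refines (the package asserts ≤ 2% error at 1-mm spacing).

Measurements mirror the clinical pipeline: within each known compartment,
muscle keeps pixels > −15 HU and fat keeps pixels in [−190, −30] HU (the
fat window is a standard adipose range, configurable, since only the
muscle threshold is conventionally fixed); areas are pixel count × pixel
area averaged over the five slices, in cm²; and eleven first-order
statistics are computed on the thresholded HU distribution by default
(switchable to the raw compartment distribution).  Numerical conventions:
percentiles interpolate linearly between order statistics; SD is the
sample SD; skewness and kurtosis are moment-based, kurtosis excess;
a constant sample has SD/skewness/kurtosis 0 by convention; an empty
sample yields all-missing statistics.  An automated quality check stands
in for manual review: fail `cut_off` when a muscle mask touches the border
margin, fail `artefact` when more than 1% of body pixels fall outside
[−500, 2000] HU.

## Record selection

When plasma creatinine is not in steady state, excretion no longer equals
production.  The daily change in total body creatinine is
`dTBCr = dPCr × VD` with `VD = 0.6 × weight` (total body water, litres);
records with |dTBCr| > 1.5 mmol/day are excluded.  The daily plasma change
is the least-squares slope over measurements within ±14 days of the scan
(a two-point first/last difference is available), since the estimator is
not conventionally fixed.  Collections outside (3, 30) mmol/day are
implausible and excluded; boundary values are retained (the published
inequalities are strict).  Consecutive collections are averaged.  Repeat
scans of a subject within 7 days are deduplicated keeping the earliest,
with greedy left-to-right chaining — a deterministic reading of the
one-week rule.  Records with an empty plasma series are treated as steady
(the donor situation).  A record with missing weight is excluded as
`nonsteady_unevaluable` only when its drift could exceed the limit at a
conservative 150-kg bound; flatter series are steady at any plausible
weight, which keeps the filter from deleting the very records the
imputation stage exists to handle.

## Multiple imputation

Weight and stature are imputed by chained-equations predictive mean
matching: per variable, a Bayesian draw of the regression parameters over
complete cases (type-1 matching), prediction of the missing cases, and a
random donor among the k = 5 observed cases with the nearest predicted
mean.  m = 10 independent chains of 20 sweeps; every imputed value is an
observed donor value, and observed cells are never altered.  The
imputation model's predictor pool defaults to the clinical variables,
compartment areas, mean attenuations and the outcome; a linear PMM model
over the full 200+ column radiomics pool is numerically fragile when
predictors approach the number of complete cases, so the full pool is
opt-in.  Iteration count, donor count and matching type are this package's
documented defaults, not published settings.

## Equation development

Per imputed development table, predictors are standardised and a LASSO is
fitted with the penalty chosen by internal 10-fold cross-validation
(CV-minimum by default; the one-SE rule is available and is the better
choice for sparse-recovery experiments over very wide pools).  Variables
selected in strictly more than half of the m imputations form the
consensus set.  Backward elimination then walks from the full consensus
set to a single variable, at each step dropping the variable whose removal
gives the lowest mean CV RMSE — averaged over folds *and* imputations,
with one fold assignment shared across imputations so between-imputation
spread reflects imputation, not fold noise.  The chosen subset is the
global minimum of the path; ties (within 1e-12 absolute / 1e-10 relative)
resolve toward the smaller model, which makes the noise-free limit
well-defined: with zero noise every truth-containing subset has CV RMSE at
machine precision, and the tie rule returns exactly the generating
support.  Final coefficients are ordinary least squares on the raw scales
per imputation, averaged over imputations; pooled SEs combine the mean
within-imputation variance with (1 + 1/m) times the between-imputation
variance.  Splits are by subject, never by record, so repeat scans cannot
leak across the development/validation boundary.

## Comparators

Cockcroft–Gault excretion: `(28 − 0.2 × age) mg/kg/day × weight`, × 0.85
for women — the age-linear excretion rule rather than back-calculation
from clearance, which the source texts leave ambiguous.  Ix:
`879.89 + 12.51 × weight − 6.19 × age − 379.42 × [female]` mg/day with the
race term set to zero when ethnicity is unrecorded.  Both convert to
mmol/day via the creatinine molar mass 113.12 g/mol.  Coefficients live in
a versioned JSON constants file with citations rather than in code.

## Validation statistics

MPE is mean(predicted − observed) — positive MPE means overestimation;
R² is the least-squares R² of observed vs predicted (identical under
either regression ordering for a single predictor); RMSE and MAPE are
standard; p15/p30 are the percentage of predictions within 15%/30% of the
observed value, thresholds inclusive.  Confidence intervals: per
imputation the metric's variance is estimated by bootstrap over records
(1000 replicates by default); the pooled point is the mean over
imputations and the total variance is mean(within) + (1 + 1/m) ×
var(between), with a normal 95% interval (z = 1.96), the same normal
approximation applying to p15/p30.  A percentile-bootstrap interval is
available behind a flag.  RMSE differences between equations are paired:
each bootstrap replicate resamples records once and evaluates both
equations on the same resample (unpaired available), which is what makes
narrow ΔRMSE intervals possible for strongly correlated prediction errors.
Tertile analysis stratifies at the empirical 33.3%/66.7% quantiles of
observed excretion, ties to the lower stratum.  Intraindividual
variability is the unweighted mean of per-donor sample SDs over donors
with ≥ 2 collections.

## Problem sizes and defaults

The default pipeline simulates 650 patient subjects and 290 donors,
renders per-record phantoms at 2-mm spacing, uses m = 10 imputations and
1000 bootstrap replicates, and completes in well under ten minutes on one
CPU.  Test-suite experiments use smaller cohorts (200–1000 subjects,
200-replicate bootstraps) chosen so each statistical check retains clear
power; the coverage experiment uses n = 300, m = 5 and 200 bootstrap
replicates over 200 simulation replicates.

## What passing tests do and do not show

The generator reproduces the *marginals and correlation strengths* of a
real cohort, not its physiology: no disease processes, no renal clearance,
no plasma-creatinine kinetics beyond the linear drift the filter needs,
and radiomics nuisance columns whose covariance is invented.  Passing
recovery tests therefore demonstrates that the pipeline's statistics do
what they claim under the stated model — unbiased pooling, nominal CI
coverage, consistent support recovery when effects are well separated —
but says nothing about how well any particular fitted equation would
transfer to real patients.  Known limitations: the one-week dedup rule and
the plasma-slope estimator are deterministic choices among several
readings of the published procedure; LASSO at the CV-minimum penalty
over-selects in wide pools (expected behaviour, hence the one-SE option);
and compartment HU distributions are unimodal truncated normals, so
threshold segmentation is an easier problem here than on real images.
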