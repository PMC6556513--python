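# Methods

## The detection problem

The unit of inference is the *patient-period*: all scans of one patient
acquired before (class 0) or after (class 1) the start of treatment at
t = 0. The question the pipeline answers is whether a classifier can tell,
from the directions of change of imaging-derived features, which period a
set of scans came from — i.e. whether the treatment leaves a detectable
imaging signature — and how much better it does so when given hundreds of
regional features rather than a handful of global aggregates.

## Trajectory features

For each feature and period, an ordinary least-squares slope is fitted to
feature value against scan time (years). Only the sign is kept: +1, −1, or
0 for an exactly zero slope (attainable by ordinal or bounded variables;
continuous features hit it with probability zero, so no tolerance band is
applied). Slope magnitudes are deliberately discarded: estimates from two
scans a month apart and five scans over six years are incomparably
reliable, and keeping magnitudes would let acquisition timing bias the
models. Left/right homologous trajectories are summed into a net trajectory
in {−2 … +2}, halving the dimensionality on the grounds that the disease
shows little systematic lateralisation. Periods need ≥ 2 scans; shorter
periods are skipped. A scan at exactly t = 0 belongs to neither change
regime and is excluded with a warning.

The low-dimensional predictor set is the trajectories of total brain
volume, total lesion volume and lesion count (each also evaluated alone);
the high-dimensional sets are the 72 collapsed regional-volume and the 72
collapsed regional-disconnection trajectories.

## Confounder removal and its verification

Volumes (regional, total brain, total lesion) are divided by that scan's
total intracranial volume. Every imaging feature is then regressed on the
covariate design — continuous covariates standardised, categorical ones
one-hot encoded with the reference level dropped — with a Bayesian ridge
regression (conjugate Gaussian model; the penalty is set by evidence
maximisation, `sklearn.linear_model.BayesianRidge` defaults). The feature
is replaced by residual + grand mean, keeping its original scale. The fit
uses all scans, including those of patients later excluded for having too
few scans per period. `residualize_features(..., regularization=<float>)`
substitutes a fixed-penalty ridge; near zero this reproduces the exact OLS
residual, which the tests exercise against a closed-form hat-matrix oracle.

Removal is verified adversarially: each confounder is dichotomised (below
sample mean vs. not; modal manufacturer vs. rest; 1.5 T vs. 3.0 T; slice
thickness < 6 mm vs. not) and an RBF-SVM is asked to predict the binarised
label from the per-scan feature vector under the same subject-level
bootstrap CV used everywhere else. Feature columns are z-scored first:
their raw scales span five orders of magnitude and an RBF kernel on raw
scales effectively sees only the largest-scale features. Covariates that
advance deterministically with time (age) are binarised at their value at
treatment start; otherwise the verification target would time-correlate
with the treatment signal the features legitimately carry, and "confounder
predictable" would conflate two different things.

Two systematic deviations from AUC = 0.5 are *expected* in this design and
documented here because they surprise at first sight. First, out-of-fold
CV on a dataset with no usable signal is mildly pessimistic: train and test
class proportions anticorrelate within a fixed pool, biasing null AUCs a
few points below 0.5. Second — and more strongly — residualisation zeroes
the pooled feature–covariate correlation *exactly*, so whatever chance
correlation the classifier exploits in its training patients is
arithmetically anti-mirrored in the held-out patients; after
residualisation the verification AUCs therefore sit systematically *below*
chance. Neither effect indicates residual confounding, so verification
checks that no confounder is predicted *above* chance (a one-sided
criterion), not CI containment of 0.5.

## Classifiers and cross-validation

Two fixed-hyperparameter families: an SVM with Gaussian RBF kernel, C = 10,
γ = 1/n_features, balanced class weights; and extremely randomised trees
with 100 trees, Gini splits, √n_features candidate features per split,
balanced class weights. No hyperparameter search. Continuous scores in
[0, 1] are the fraction of trees voting class 1 (ERT) or a logistic
transform of the decision value (SVM); class decisions threshold at 0.5.

Evaluation is Monte-Carlo cross-validation: at each of n_iter iterations
(500 by default; 100 in the test suite and driver for tractability) a
random 80/20 partition **of patients** is drawn — never of vectors, so the
two periods of a both-period patient cannot straddle the split — the model
is fitted on the training vectors and scored on the fully held-out test
vectors. Partitions are without replacement within an iteration; a split
whose training side lacks a class is redrawn (bounded retries). Per-
iteration AUC, accuracy, sensitivity, specificity, balanced F (the F1
harmonic mean) and MCC (0 when a denominator factor vanishes; positive
class = post-treatment) are aggregated as mean ± 1.96·sd/√n_iter. AUC is
recorded as missing for the occasional single-class test set and excluded
from aggregation. Every held-out score enters an out-of-fold ledger keyed
by vector; consensus predictions threshold each vector's mean out-of-fold
score (ties to class 1). An optional `balance="subsample"` mode randomly
drops majority-class training vectors to the minority count.

Greedy forward-stepwise selection starts from the single feature with the
highest mean out-of-fold AUC and adds, at each step, the candidate that
maximises the augmented set's mean AUC; every evaluation reuses the same
seed, hence the identical split sequence, making candidate comparisons
paired. The chosen model size is the argmax of the cumulative mean AUC
(ties resolve to the smaller set). Selection is run once and reused.

The high-dimensional ensemble averages the volume-model and
disconnection-model scores weighted by their mean AUCs. It is computed from
the two components' out-of-fold ledgers, which requires both to have been
run with the same seed (identical splits); the constructor verifies this.

## Permutation null

Each patient's per-feature value series is randomly permuted across that
patient's scan times (times and covariates untouched), independently per
feature. Slope signs then carry no temporal information while scan timing,
value marginals and the class structure are all preserved, so any residual
"detection" would reflect timing artefacts. Null mean AUCs are expected in
a chance band (≈ 0.40–0.60 at this cohort size), not at exactly 0.5, for
the CV-pessimism reason above.

## Simulated randomised controlled trials

A trial of size N samples N distinct patients (without replacement; an RCT
enrols distinct people), pools all their trajectory vectors into a 2×2
table of consensus prediction × true period, and computes Fisher's exact
two-sided p and the sample odds ratio (Haldane–Anscombe +0.5 correction
when any cell is zero; p = 1 for a degenerate margin). Over 500 repetitions
(200 in tests) per N this yields the mean OR ± 1.96 SE and the *achieved
power*: the rejection fraction at α = 0.01, with a Wilson binomial CI.
Power is estimated empirically by rejection counting rather than through an
analytic power calculator: it is the same estimand without a dependence on
an external tool's approximation.

## The synthetic cohort generator

The generator emulates the per-scan feature tables of a natalizumab-treated
relapsing–remitting MS cohort imaged under routine heterogeneous protocols.
Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_pre_only / n_post_only / n_both | 16 / 60 / 27 | patients with ≥2 scans only before / only after / in both periods (103 patients, 130 trajectory vectors, 33.1% class 0) |
| scans_per_period | 2–5 | uniform; the per-study scan count is not a target |
| time_window_years | (3, 4) | pre scans in [−3, −0.1] y, post in [0.1, 4] y; nothing at t = 0 |
| n_region_pairs | 72 | 144 volume + 144 disconnection variables per scan |
| affected_fraction | 0.3 | region pairs carrying a treatment-modulated slope (cohort-level set) |
| pre/post volume slope | −40 ± 10 / +10 ± 5 mm³·y⁻¹ | atrophy then stabilisation/recovery in affected regions |
| pre/post disconnection slope | +0.02 ± 0.005 / −0.005 ± 0.003 y⁻¹ | mirrored signs |
| noise_sd / disc_noise_sd | 50 mm³ / 0.025 | per-scan measurement noise; the standardised post−pre slope change is ≈ 1 noise-sd·y⁻¹ per region |
| global_slope_sd / disc_global_slope_sd | 15 mm³·y⁻¹ / 0.0075 y⁻¹ | per-patient-period slope component shared by all regions of a modality |
| lesion rates | 1.0 / 0.05 y⁻¹ | Poisson new-lesion arrivals pre / post; counts observed with sd-1.5 rounding noise, volume ∝ count |

The *global slope component* models brain-wide physiological variability
(hydration-like shifts) common to all regions of a patient-period. It is
what separates the two dimensionality regimes: summed into total brain
volume it dominates the aggregate's sign, capping the low-dimensional
models near chance, while the regional *pattern* (affected vs. unaffected
regions) survives it. Both modalities carry a global component of the same
relative size so that the volume and disconnection models are comparably
strong and their AUC-weighted ensemble is a genuine average of peers.
Covariates follow realistic scales (age ≈ N(38, 10) advancing with scan
time; EDSS ≈ N(4.8, 1.7) and disease duration ≈ N(6.3, 2.2) fixed at
treatment start; manufacturer/field strength/slice thickness/voxel
resolution resampled per scan); confounders act additively and linearly on
the features with region-specific susceptibility, the largest effects
assigned to scanner manufacturer and field strength. Disconnection
baselines are drawn U(0.2, 0.5), away from the [0, 1] bounds, so clipping
(which would make the confounding nonlinear and unremovable by a linear
model) is negligible.

`strong_effect_config()` is a preset for feature-recovery experiments:
12 region pairs, 4 affected, a ≈1.8 noise-sd·y⁻¹ standardised effect, no
confounding, and 75 patients — large enough that single-feature AUC
rankings are stable and recovery measures the selection algorithm rather
than cohort-size luck.

What the generator does **not** emulate: spatial correlation between
regions beyond the global component, non-linear covariate effects,
scanner×region interactions, pseudoatrophy dynamics, drop-out that depends
on disease course, or any image-level process. Passing tests therefore
demonstrate that the pipeline detects the intended statistical structure
and rejects its absence — not that real MRI data carry that structure.

## Numerical choices and degenerate inputs

* 95% CIs are mean ± 1.96 SE throughout (bootstrap SE across iterations;
  Wilson for power proportions).
* Kolmogorov–Smirnov model comparison uses the exact null below a combined
  n of 25, asymptotic otherwise; significance at 0.05.
* Exactly-zero slopes map to trajectory 0 only under exact floating
  equality.
* TIV ≤ 0, missing covariates, < 2 scans for a slope, zero time variance,
  duplicate (patient, time) keys and empty cohorts raise immediately with
  named errors.
* All randomness flows from `numpy.random.default_rng(seed)`; generation,
  CV, selection, nulls and RCTs are bit-reproducible given their seeds, and
  the experiment driver writes a manifest from which the whole bundle
  regenerates bit-identically.

## Scale of the shipped experiments

The test suite and driver run the full 103-patient, 72-pair cohort with
100-iteration CV for the SVM family, the permutation null, the adversarial
verification and the RCT grid, and a 75-patient strong-effect cohort for
selection recovery; the ERT family is exercised on reduced cohorts. These
sizes keep the complete suite in the minutes range while leaving every
qualitative contrast (high vs. low dimensional, real vs. null, power
growth with N) comfortably outside its CI noise.
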