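# Methods

## The model

The package predicts a binary outcome — mild cognitive impairment (MoCA
< 26) in elderly COPD patients — from 20 clinical and laboratory features.
The classifier is a two-stage *residual fusion*:

1. **Linear stage.** A penalized logistic regression is fitted on
   standardized, *weighted* features and emits a class-1 probability
   `p(x)`.  The published description calls this stage "linear regression
   (LR)" but also assigns it a penalty-type hyperparameter (L1 or L2) and a
   binary task; we therefore implement it as penalized logistic regression
   and treat this as the central interpretive decision of the
   implementation.  Residuals are `r = y − p ∈ (−1, 1)`.
2. **Residual stage.** An ε-insensitive support-vector regressor with an
   RBF kernel (ε = 0.1, configurable) is fitted on `(x_w, r)`.  Residuals
   are continuous, so the regression variant of the SVM is the natural
   choice.
3. **Fusion.** The final score is `clip(p + r̂, 0, 1)`; hard labels use a
   0.5 threshold.  Whether the original system clipped, renormalized or
   thresholded the fused sum is unstated; clipping is the simplest choice
   that keeps scores probability-like.  If the residual stage predicts
   exactly zero the fusion reduces to the linear stage (this identity is
   tested to machine precision).

### Joint encoding and the objective

A single *decision vector* in `[0,1]^(n_features+4)` carries one importance
weight per feature (genes 1–20) and four hyperparameters: the logistic
regularization strength `C_lr`, its penalty type, the SVR penalty `C_svm`
and the RBF `gamma`.  Continuous hyperparameters map to `[0.01, 100]` on a
log10 scale — they are scale parameters spanning four decades, so a uniform
gene would otherwise spend half its range above 50.  The penalty gene splits
at 0.5 (≥ 0.5 → L2).

Features are z-score standardized *before* weighting; otherwise a weight
conflates measurement units with importance.  Whether the original pipeline
standardized is unstated; we document the choice here.  Standardization
parameters are always estimated on training folds only.

The objective maximized by the optimizers is the mean stratified k-fold
cross-validated ROC-AUC of the fused model (default k = 5; the source
describes its cross-validation ambiguously, and 2-fold would contradict its
stated stability goal, so 5-fold is the default and the count is
configurable).  Fold assignment is *content-canonical*: rows are put in a
deterministic order derived from the feature values of the nonzero-weight
columns before the seeded within-class shuffle.  This makes the objective
invariant to row order and makes "weight = 0" exactly equivalent to
deleting the column.  The top-k contribution analysis pins the full-model
fold assignment across all k so curve points are comparable.

## Optimizers

Six box-constrained, elitist, maximizing metaheuristics share one
interface (population 50 × 50 iterations by default, matching the published
protocol; every constant is overridable through `algo_params`):

- **CSA** (circle search): `X_i ← X* + (X* − X_i)·tan(θ_i)` with
  `θ_i = w·U(0,1)` after a fraction `c = 0.8` of the budget (exploitation)
  and `θ_i = w·p` before it, where `w = π − π(t/T)²`,
  `p = 1 − 0.9√(t/T)`.  The source gives only the tangent principle; the
  schedule follows the algorithm's original exploration→exploitation
  design.
- **GA**: real-coded, tournament size 3, BLX-0.5 crossover, Gaussian
  mutation (σ = 0.1 box width), one elite.
- **PSO**: global-best, inertia 0.9→0.4 linear, c1 = c2 = 2, velocity
  clamped to 0.2 × box width.
- **SA**: one annealing chain per population slot (budget parity with the
  population methods), Gaussian proposals scaled by box width × relative
  temperature, exponential cooling (0.9), Metropolis acceptance.
- **SSA** (sparrow): producer fraction 0.2, scout fraction 0.1, alarm
  threshold 0.8, standard position updates.
- **TSO** (tuna): spiral and parabolic foraging chosen per individual,
  spiral constant b = 0.05, re-seed probability z = 0.05.

None of these constants are stated in the source for this application; all
follow the algorithms' conventional forms.  Out-of-bounds candidates are
hard-clipped.  Every optimizer records a best-so-far history (monotone by
construction) and is bit-reproducible from its seed; repeated-run batches
use `seed + run_index`.

## Synthetic cohorts

No patient data accompany the published study, so a generator emulates the
cohort (863 patients: 356 impaired / 507 normal; external set 114/219).

- **table8 mode** fixes the group sizes and draws the eight informative
  features from class-conditional distributions parameterized by the
  published group summaries: Gaussians for age (69.23 ± 2.34 vs
  62.38 ± 2.13 years), course of disease, PaCO2, Hcy, ET-1 and
  25-hydroxyvitamin D (truncated at physiologic floors by resampling), and
  categorical draws for GOLD stage (4 levels) and education (2 levels)
  from the published per-level counts.  The 12 nuisance features are
  class-independent with prevalences 0.3–0.6 (binary) or plausible
  ward-population Gaussians (BMI, PaO2, admissions).
- **mechanism mode** draws features first (pooled distributions) and
  generates the label from a logistic mechanism: log-odds linear in the
  eight informative features (standardized coefficients 0.7–1.0 in
  absolute value, signs clinically oriented) plus
  `strength × (z_age·z_PaCO2 + tanh(2·z_ET1))`.  The default strength is
  4.0, chosen so the nonlinear component dominates the linearly
  inaccessible part of the signal (ground-truth AUC of the full log-odds
  ≈ 0.98 against ≈ 0.77 for its best linear part): mechanism mode exists
  precisely to test whether the residual stage captures structure the
  linear stage cannot, and at weak strengths that question cannot be
  answered at this cohort size because the ε-SVR cannot recover a small
  nonlinear increment from n ≈ 860 Bernoulli-noisy residuals.
  With `strength = 0` the log-odds are exactly linear and the fused model
  is expected to match its linear stage (tested).

What the generator does **not** emulate: missing data, measurement error,
feature correlations within class (features are conditionally independent),
longitudinal structure, or site effects beyond a configurable mean shift
(external mode shifts continuous means by 0.25 within-class SD).  Passing
tests therefore demonstrate correctness of the machinery and the claimed
qualitative orderings under a favorable, known mechanism — not clinical
performance on real cohorts.

The external-validation group sizes follow the published subgroup counts
(114 + 219 = 333) rather than the stated total of 317; the two figures are
inconsistent in the source and the subgroups are what the metrics need.

## Evaluation and statistics

The metric suite reports PRE/SEN/SPE/ACC/ER/F1 at a stated threshold plus
ROC-AUC (Mann-Whitney rank form; ties count one half) and PR-AUC
(average-precision step convention — PR-space trapezoids interpolate
optimistically; the convention is switchable by calling scikit-learn
directly).  Zero-denominator ratios are reported as 0 with a `degenerate`
flag rather than raising, so batch evaluations survive degenerate folds.

Group comparisons use the pooled-variance two-sample t-test and Pearson's
χ² without continuity correction.  These exact conventions were selected
because they reproduce the published group-comparison statistics from the
printed summaries (pooled t: age 44.643, course 10.863, Hcy 2.863, ET-1
37.253; χ²: education 71.459, GOLD stage 70.985); Welch's t and the
Yates-corrected χ² do not.  Two published values (PaCO2 t = 28.292,
25-hydroxyvitamin t = 11.035) are not reproducible from their own printed
summaries under any standard formula (recomputation gives 28.09 and 14.92);
they are left as-is and excluded from reproduction checks rather than
"fixed".

## Interpretability

Weights are ranked descending (ties keep feature order).  The top-k
contribution curve zeroes all but the k highest-weighted features
(hyperparameters frozen — whether the original refit them per k is
unstated, and freezing isolates the weights' contribution) and re-evaluates
both AUCs on the pinned fold split.  The selected feature count is the
smallest k after which no step gains ≥ ε ROC-AUC (ε = 0.01 by default; the
source's "no longer substantially improved" is not quantified).

## Problem sizes used in the test and acceptance suites

Full-fidelity runs (population 50 × 50 iterations × 30 repeats × 5 folds)
are hours of compute; the suites use reduced but structurally identical
protocols, chosen as the smallest sizes at which each property is
statistically decidable: sphere benchmarks at the published 50 × 50 budget
(they are cheap); the fusion-vs-linear comparison with CSA at population
20 × 20 iterations, 3 folds, 10 seeds, evaluated on an independent
3 000-patient draw from the same mechanism so the AUC difference is
measured with ~0.008 standard error instead of ~0.03 on a 173-patient
split; the contribution-curve and generator-recovery properties at 3 folds
and 10 seeds.  The end-to-end `compare` command is exercised once at
population 10 × 10 iterations on a 400-patient cohort.

## Known limitations

- Weight-based importance ranking is only partially identifiable: the
  cross-validated AUC objective changes by roughly its own noise floor
  (~0.005) when a weak-effect feature (e.g. Hcy at Cohen's d ≈ 0.2) is
  removed, so the wrapper cannot reliably separate such features from
  nuisance at any affordable budget — larger populations simply drive
  weights to the box bounds without resolving the ordering.  The
  contribution-curve and plateau analyses therefore accept an externally
  supplied ranking rather than assuming the optimizer's ranking is perfect,
  and the package makes no claim that all eight informative features top
  the learned ranking.
- The ε-SVR residual stage scales as O(n²)–O(n³); cohorts beyond ~10⁴ rows
  would need subsampling or a linear-time kernel approximation.
- Scores, although clipped to [0, 1], are not calibrated probabilities.
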