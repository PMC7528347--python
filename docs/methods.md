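# Methods

## The problem

In biomedical prediction tasks — toxicogenomics, differential expression,
epidemiological cohorts — the association between molecular features and a
clinical target is routinely distorted by covariates: batch, compound
treatment, dose, sacrifice time, sex, study. The standard biostatistical
remedy is *residualization* ("regressing out"): fit a model predicting the
variable of interest from the covariates and replace the variable by its
residuals. Inside a cross-validated model search this is subtle: residuals
computed from a whole-dataset covariate fit inject information about test
rows into training (*leakage*), inflating cross-validation scores and
degrading generalization. `resadj` implements residual adjustment that is
leakage-free by construction: for every CV split, covariate models are
fitted on that split's training rows only and then applied to all rows.

## Residual model

For a variable `v` adjusted by covariate columns `C`:

- continuous `v`: ordinary least squares with intercept, fitted on the
  training rows; residual `r_i = v_i − ŷ_i`. Rank-deficient designs (e.g.
  collinear encoded covariates) are solved by the minimum-norm solution,
  never an error, because degenerate designs are routine inside an
  automated search.
- binary / multiclass-ordinal `v`: multinomial logistic regression with
  intercept; residual `r_i = v_i − Σ_k c_k · p̂_ik`, the observed value
  minus the probability-weighted class value. Class values are the sorted
  numeric codes observed on the training rows (dose levels 1–4, a 7-level
  clinical-chemistry grade, …). A ridge penalty of strength 1e-4 on the coefficients
  (not the intercept) guarantees convergence under separation, which small
  CV folds produce regularly; this is a deliberate, documented deviation
  from plain maximum likelihood, and it means a saturated fit reproduces
  empirical cell proportions to ≈1e-4 rather than exactly. If a training
  fold contains a single class, the predicted probability is identically 1
  for that class and the residual is `v − class_value`; no error.

Orthogonality is exact for the continuous case: training-row residuals
have mean zero and zero sample covariance with every covariate column (to
machine precision; tests assert < 1e-8).

## Data model and the per-split target

The search engine consumes an augmented table built by the target
pre-processor. For each of the predefined CV splits *i* it appends

- `__split{i}_indicator` — 1 train, 0 test, −1 row not in the split;
- `__split{i}_residual` — target residuals from a covariate model fitted
  on split *i*'s training rows only;

plus one `__full_residual` column from a whole-input fit, used exclusively
for the final refit after the search has ended. A component inside the
search recovers "its" split by exact row-set matching (`identify_split`):
the row set it was handed must equal exactly one split's train set (fitting
context) or test set (scoring context), or all rows (FULL, final refit).
Ambiguity is an error, never a heuristic match — silently training against
the wrong residual column would be the worst possible failure mode. Every
lookup is logged, which lets tests assert the no-leakage invariant that no
FULL lookup occurs while the search is still inside CV.

An optional holdout set is removed before anything else, appears in no
split and influences no fitted model; its target is residualized by the
model fitted on all non-holdout rows, and it serves only to score the
final pipeline and to compute permutation importance.

Split plans: `shuffle` draws independent train/test partitions (default 5
splits at 75 % train) and `kfold` partitions the rows; both are
reproducible from a single seed and serializable, so an adjusted and an
unadjusted analysis can share identical splits.

## Encodings

Nominal variables enter regressions via two schemes: `one_hot_drop_first`
(N categories → N−1 dummies, first category is the reference) for small N,
and `base2_binary` (ordinal codes 1..N written in binary over
⌈log₂(N+1)⌉ columns, most-significant bit first) for high-cardinality
variables — 41 categories fit in 6 columns. An explicit category order is
honored in full, including declared-but-unobserved categories, so
encodings agree across data subsets; without one, first-appearance order
is used. Encoding happens once, up front, before any split is drawn;
encoded columns inherit the covariate (or feature) role.

## Pipeline search

Pipelines are typed operator sequences matching a template, e.g.
`FeatureSetSelector-resAdjTransformer-Transformer-Regressor`. The
FeatureSetSelector restricts features to one named set (a pathway); the
resAdjTransformer refits feature residual models on the rows it is handed
(one split's training rows during CV, all rows at the final refit),
applies them, and drops the covariate columns before the data flows on; it
must be the first step or immediately follow the FeatureSetSelector.

The optimizer is a compact seeded genetic program: random initial
population, per-step hyperparameter mutation and operator-swap mutation
(rate 0.9), one-point crossover (rate 0.1), single-individual elitism, and
binary-tournament parent selection under two-objective dominance
(maximize CV score, minimize step count). The reported winner is the
highest-scoring individual, ties broken by lower complexity then earlier
creation, refit on all non-holdout rows. Pipelines that raise during
fitting score −∞; a fully invalid generation aborts with diagnostics.
Identical (pipeline, split-plan) evaluations are memoized within a run —
a pure optimization with no semantic effect.

The default operator pool is deliberately small and deterministic —
variance-threshold and percentile selectors, scaling and degree-2
polynomial transformers, linear/ridge and shallow-tree estimators, and
penalized logistic / tree classifiers — so that desk-scale searches are
honest explorations of a finite space rather than lottery draws from a
large one. The pool is extensible via `OperatorPool`.

Scoring: R² (or negative MSE) against the split's residual target in
adjusted mode; in classic (unadjusted) mode the raw target is used, with
balanced accuracy — the unweighted mean of per-class recall — for
multiclass ordinal targets. Both modes run the identical engine.

## Permutation importance

For a fitted pipeline, each input column (features and, in adjusted mode,
the covariates its residual models consume) is shuffled across the holdout
rows `n_repeats` times (default 10, seeded); the importance is the base
holdout score minus the mean permuted score. Columns provably outside the
pipeline's inputs are exactly 0. Negative decreases are retained; clipping
would bias aggregates. Across independent runs, per-run percentages
(100 · decrease / testing score) are averaged weighted by testing score;
runs with non-positive testing scores are excluded and counted.

## Diagnostics

To judge whether a covariate is worth adjusting for: k-means (10 seeded
restarts per k) is swept over a k range, the clustering maximizing the
Dunn index (minimum intercluster distance / maximum intracluster diameter,
Euclidean throughout) is kept (ties → smaller k), and the homogeneity of
that clustering with respect to each candidate annotation is summarized by
the BHI — the average over clusters (≥2 members; singletons skipped,
switchable to pooled-pair weighting) of the fraction of within-cluster
pairs sharing the annotation. Degenerate Dunn conventions: all clusters
singletons → +∞ with a warning; all points identical (0/0) → 0.

## Synthetic data

The generator emulates a confounded toxicogenomics design: `m=300`
samples; 10 feature sets × 12 continuous features; a nominal compound
covariate with 8 levels (emitted as labels and as 4 base-2 bit columns);
ordinal dose and time covariates with 4 levels each; a confound signal
`h` = standardized seeded linear combination of the encoded covariate
columns. Background features are N(0, 1); the *decoy* set's features are
`β_confound·h + N(0, σ)`; the latent target is
`β_signal·mean(true-set features) + β_confound·h + N(0, σ)`; the default
target discretizes the latent variable at its empirical septiles into 7
balanced ordinal levels. Defaults `β_signal = 2.0`, `β_confound = 2.0`,
`σ = 0.5`.

Why these effect sizes: the target loads on the *mean* of the true set, so
each individual feature carries only 1/12 of the set-level association,
and the ordinal discretization plus the per-split residual noise of the
7-class logistic target model attenuate it further. β_signal = 2 makes the
true set's CV R² ≈ 0.25 on residualized data — a clear but not trivial
signal, the regime the method is for — while β_confound = 2 makes the
decoy set explain most of the raw target variance, so the unadjusted
search is reliably captured by the decoy. What the generator does *not*
emulate: heavy-tailed expression noise, probe-level measurement error,
correlated features within a set, overlapping pathways, nonlinear
covariate effects. Passing recovery tests therefore demonstrates the
leakage-free machinery and the adjusted-vs-classic contrast under an ideal
linear-confounding regime, not performance on real microarray data.

## Problem sizes

The recovery experiments run the full preprocess → search → holdout chain
with population 20, generations 5, 5 CV splits at 75 % train, 25 %
holdout, 20 runs per mode (10 per mode for the zero-confounding
concordance check), with each run drawing fresh holdout/split seeds over a
single simulated dataset. These sizes make the contrast reproducible in a
few minutes on one core; they are the package's desk-scale defaults, and
all of them scale up by argument.

## Numerical conventions

- float comparisons in tests: 1e-8 absolute unless a looser tolerance is
  stated (ridge-penalized logistic: 1e-3);
- covariates are numeric after encoding, so residual models extrapolate
  to unseen covariate patterns without special handling;
- all randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; run-level seeds are derived as
  `base_seed + 7919·(run+1) mod 2³¹`.

## Known limitations

- Only linear/logistic residualization is provided; alternative
  residualizing estimators (trees, splines) are out of scope.
- No nested CV and no stratified splitting.
- `identify_split` requires the engine to present exactly a split's rows;
  external estimators that subsample internally would not be able to
  recover their split.
- The GP's multi-objective selection degenerates to score-only when the
  template fixes the step count, which is the common case here.
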