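# resadj

Leakage-free covariate adjustment for cross-validated automated pipeline
search.

## Who this is for

Biostatisticians and bioinformaticians who want to ask "which features
(genes, probesets, pathways) predict this outcome?" with an automated,
cross-validated pipeline search — while *adjusting for covariates* such as
batch, compound treatment, dose, sacrifice time, sex or study. Adjusting
is standard in epidemiology but subtle inside machine learning: the usual
shortcut of regressing covariates out of the whole dataset before
cross-validation leaks test-row information into training and inflates CV
scores. `resadj` does the adjustment correctly, split by split.

## The core idea

To adjust a variable *v* (a feature or the target **y**) for covariates,
fit a predictor of *v* from the covariates — linear regression if *v* is
continuous, multinomial logistic regression if it is binary or multiclass
ordinal — and replace *v* by its residuals:

```
continuous:   r_i = v_i − ŷ_i
categorical:  r_i = v_i − Σ_k c_k · p̂_ik     (probability-weighted class values)
```

The leakage-free rule: **for every CV train/test split, the covariate
model is fitted on that split's training rows only**, then applied to all
rows. For features this happens inside the pipeline (a residual-adjustment
transformer that also drops the covariate columns); for the target, a
pre-processor materializes per-split indicator and residual columns into
the table so any downstream component can recover the correct adjusted
target for the split it is inside. On top of this sit:

- a template-constrained, fully seeded genetic-programming search over
  scikit-learn pipelines with a Feature Set Selector (pathway-style
  feature sets, GMT files);
- permutation importance on holdout rows with score-weighted aggregation
  across independent runs;
- covariate-relevance diagnostics (Dunn-index k-means sweep + Biological
  Homogeneity Index);
- a synthetic-data generator with planted ground truth (true signal set vs
  covariate-driven decoy set) so every claim above is testable end to end.

## Worked example

```python
from resadj import SimConfig, run_once, simulate

cfg = SimConfig(seed=0)        # 300 samples, 10 sets x 12 features, strong confound
table, collection, amap, truth = simulate(cfg)
adj = run_once(table, collection, amap, "adjusted", seed=11)
cls = run_once(table, collection, amap, "classic", seed=11)
print(truth.true_set, truth.decoy_set)
print(adj["selected_set"], adj["holdout_score"])
print(cls["selected_set"], cls["holdout_score"])
```

prints (see `examples/03_search_contrast.py`):

```
planted truth: signal in set00, confounded decoy set01
adjusted  search selected set00 (CV R2=0.282, holdout R2=0.428)
classic   search selected set01 (CV bal.acc=0.469, holdout bal.acc=0.458)
```

The generator planted the real signal in `set00` and made `set01` a decoy
driven by the same covariates that drive the 7-level ordinal target. The
unadjusted ("classic") search is captured by the decoy — it predicts the
raw target well (balanced accuracy 0.46 vs the 1/7 ≈ 0.14 chance level)
for entirely confounded reasons. The adjusted search residualizes features
and target per split, the decoy's advantage evaporates, and the true set
is selected with a holdout R² of 0.43 against the residualized target.

The other scripts in `examples/` walk the individual capabilities:
residualization and its no-leakage guarantee (`01`), the pre-processor's
indicator/residual columns and split identification (`02`), permutation
importance and aggregation (`04`), and the Dunn/BHI covariate diagnostics
(`05`). A thin CLI mirrors the library:
`resadj simulate|preprocess|search|importance|diagnose --help`.

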