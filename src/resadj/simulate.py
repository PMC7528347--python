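"""Confounded expression-like data with known ground truth.

The generator emulates the structure of a toxicogenomics expression study:
continuous features grouped into pathway-style feature sets, a nominal
compound covariate (emitted both as labels and pre-encoded base-2 bit
columns), ordinal dose and time covariates, and a target that is either
continuous or a 7-level ordinal.  One *true* feature set carries the real
signal into the target; one *decoy* set is driven by the covariates, which
also drive the target — a confound.  Without adjustment the decoy set
predicts the target better than the true set; after residualizing features
and target on the covariates, only the true set should survive.

Defaults: m=300 samples, 10 sets of 12 features, 8 compounds, 4 dose and 4
time levels, signal effect 2.0, confound effect 2.0 (strong), noise SD 0.5,
7-level ordinal target.  Effect sizes are sized so the planted set is
reliably detectable at these sample counts: the target loads on the *mean*
of the true set's features, so the per-feature association is the set-level
effect divided by the set size, and a weaker signal would be invisible
after ordinal discretization and per-split residual noise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import EncodingSpec, binary_encode
from .preprocess import build_resadj_dataset, make_split_plan
from .search import ClassicDataset, Template, evolve, holdout_score, split_holdout
from .table import AdjustedTable, AdjustmentMap, FeatureSetCollection


@dataclass
class SimConfig:
    m: int = 300
    n_sets: int = 10
    set_size: int = 12
    true_set: int = 0
    decoy_set: int = 1
    n_compounds: int = 8
    n_dose_levels: int = 4
    n_time_levels: int = 4
    beta_signal: float = 2.0
    beta_confound: float = 2.0
    sigma: float = 0.5
    target_kind: str = "ordinal7"  # "continuous" | "ordinal7"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_set == self.decoy_set:
            raise ValueError("true_set and decoy_set must differ")
        if not (0 <= self.true_set < self.n_sets and 0 <= self.decoy_set < self.n_sets):
            raise ValueError("true_set and decoy_set must index existing sets")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.target_kind not in ("continuous", "ordinal7"):
            raise ValueError(f"unknown target_kind {self.target_kind!r}")
        for name in ("beta_signal", "beta_confound"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SimTruth:
    """Everything needed to recompute the generated values given the seed."""

    true_set: str
    decoy_set: str
    confound_coefficients: dict[str, float]
    feature_coefficients: dict[str, float]
    covariate_assignments: pd.DataFrame
    septile_boundaries: list[float] = field(default_factory=list)


def _set_name(i: int) -> str:
    return f"set{i:02d}"


def simulate(
    config: SimConfig,
) -> tuple[AdjustedTable, FeatureSetCollection, AdjustmentMap, SimTruth]:
    """Draw one dataset; fully reproducible from ``config`` (incl. its seed).

    Covariates are uniform; background features are standard normal; the
    decoy set's features and the latent target both load on h(covariates),
    a standardized seeded linear combination of the encoded covariate
    columns.  The adjustment map adjusts the target and every feature by
    the encoded covariates (the both-features-and-target workflow).
    """
    rng = np.random.default_rng(config.seed)
    m = config.m

    compounds = np.array([f"c{k:02d}" for k in rng.integers(1, config.n_compounds + 1, m)])
    dose = rng.integers(1, config.n_dose_levels + 1, m)
    time = rng.integers(1, config.n_time_levels + 1, m)

    order = [f"c{k:02d}" for k in range(1, config.n_compounds + 1)]
    bits = binary_encode(
        compounds, EncodingSpec("compound", "base2_binary", category_order=order)
    )
    cov = pd.DataFrame({"dose": dose, "time": time})
    cov = pd.concat([bits, cov], axis=1)

    # h: standardized linear combination of encoded covariates, seeded weights
    weights = rng.normal(size=cov.shape[1])
    raw = cov.to_numpy(dtype=float) @ weights
    h = (raw - raw.mean()) / raw.std()
    confound_coefficients = dict(zip(cov.columns, weights))

    n_features = config.n_sets * config.set_size
    feat_names = [
        f"g{s:02d}_{j:02d}" for s in range(config.n_sets) for j in range(config.set_size)
    ]
    X = rng.normal(size=(m, n_features))
    decoy_cols = [
        config.decoy_set * config.set_size + j for j in range(config.set_size)
    ]
    for j in decoy_cols:
        X[:, j] = config.beta_confound * h + rng.normal(scale=config.sigma, size=m)

    true_cols = [config.true_set * config.set_size + j for j in range(config.set_size)]
    latent = (
        config.beta_signal * X[:, true_cols].mean(axis=1)
        + config.beta_confound * h
        + rng.normal(scale=config.sigma, size=m)
    )
    septiles: list[float] = []
    if config.target_kind == "ordinal7":
        septiles = list(np.quantile(latent, np.arange(1, 7) / 7.0))
        target = np.searchsorted(septiles, latent) + 1.0
        target_kind = "ordinal"
    else:
        target = latent
        target_kind = "continuous"

    df = pd.DataFrame(X, columns=feat_names)
    df["compound"] = compounds
    for c in cov.columns:
        df[c] = cov[c].to_numpy()
    df["target"] = target
    df.index = pd.Index([f"s{i:04d}" for i in range(m)], name="sample_id")

    roles = {c: "feature" for c in feat_names}
    kinds = {c: "continuous" for c in feat_names}
    roles["compound"], kinds["compound"] = "covariate", "nominal"
    for c in bits.columns:
        roles[c], kinds[c] = "covariate", "binary"
    roles["dose"], kinds["dose"] = "covariate", "ordinal"
    roles["time"], kinds["time"] = "covariate", "ordinal"
    roles["target"], kinds["target"] = "target", target_kind
    table = AdjustedTable(df, roles, kinds)

    sets = {
        _set_name(s): (
            f"synthetic feature set {s}",
            feat_names[s * config.set_size : (s + 1) * config.set_size],
        )
        for s in range(config.n_sets)
    }
    collection = FeatureSetCollection(sets)

    encoded_covs = list(cov.columns)
    amap = AdjustmentMap(
        entries=[(f, encoded_covs) for f in feat_names],
        adjust_target=True,
        target_covariates=encoded_covs,
    )
    amap.validate(table)

    truth = SimTruth(
        true_set=_set_name(config.true_set),
        decoy_set=_set_name(config.decoy_set),
        confound_coefficients=confound_coefficients,
        feature_coefficients={feat_names[j]: config.beta_signal for j in true_cols},
        covariate_assignments=pd.DataFrame(
            {"compound": compounds, "dose": dose, "time": time}, index=df.index
        ),
        septile_boundaries=septiles,
    )
    return table, collection, amap, truth


ADJUSTED_TEMPLATE = "FeatureSetSelector-resAdjTransformer-Transformer-Regressor"
CLASSIC_TEMPLATE = "FeatureSetSelector-Transformer-Classifier"
CLASSIC_TEMPLATE_CONTINUOUS = "FeatureSetSelector-Transformer-Regressor"


def run_once(
    table: AdjustedTable,
    collection: FeatureSetCollection,
    amap: AdjustmentMap,
    mode: str,
    seed: int,
    gp_population: int = 20,
    gp_generations: int = 5,
    n_splits: int = 5,
    train_fraction: float = 0.75,
    holdout_fraction: float = 0.25,
):
    """One preprocess -> search -> holdout-score chain in either mode."""
    tkind = table.kind_of(table.target_name)
    if mode == "adjusted":
        m_work = table.m - int(round(table.m * holdout_fraction))
        plan = make_split_plan(m_work, n_splits, "shuffle", train_fraction, seed)
        data = build_resadj_dataset(table, amap, plan, holdout_fraction, seed)
        template, metric = ADJUSTED_TEMPLATE, "r2"
    elif mode == "classic":
        work, hold = split_holdout(table, holdout_fraction, seed)
        plan = make_split_plan(work.m, n_splits, "shuffle", train_fraction, seed)
        if tkind == "continuous":
            template, metric = CLASSIC_TEMPLATE_CONTINUOUS, "r2"
        else:
            template, metric = CLASSIC_TEMPLATE, "balanced_accuracy"
        data = ClassicDataset(work, plan, hold)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    best, log, fitted = evolve(
        data,
        template,
        None,
        collection,
        population=gp_population,
        generations=gp_generations,
        metric=metric,
        seed=seed,
    )
    score = holdout_score(fitted, data, metric)
    return {
        "best": best,
        "log": log,
        "fitted": fitted,
        "data": data,
        "metric": metric,
        "holdout_score": score,
        "selected_set": best.selected_set,
    }


def recover(
    config: SimConfig,
    mode: str,
    gp_population: int = 20,
    gp_generations: int = 5,
    n_runs: int = 20,
    base_seed: int = 0,
) -> tuple[Counter, list[dict]]:
    """Repeat the full chain over ``n_runs`` seeded holdout/split draws and
    tabulate which feature set each run's optimal pipeline selected."""
    table, collection, amap, _truth = simulate(config)
    counts: Counter = Counter()
    details: list[dict] = []
    for r in range(n_runs):
        seed_r = int((base_seed + 7919 * (r + 1)) % (2**31))
        res = run_once(
            table, collection, amap, mode, seed_r, gp_population, gp_generations
        )
        counts[res["selected_set"]] += 1
        details.append(
            {
                "run": r,
                "seed": seed_r,
                "selected_set": res["selected_set"],
                "cv_score": res["best"].cv_score,
                "holdout_score": res["holdout_score"],
            }
        )
    return counts, details
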