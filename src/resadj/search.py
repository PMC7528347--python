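"""Template-constrained evolutionary search over scikit-learn pipelines.

Pipelines are typed operator sequences matching a *template* such as
``FeatureSetSelector-resAdjTransformer-Transformer-Regressor``.  The search
is a small, fully seeded genetic program: a population of configured
pipelines evolves by hyperparameter mutation, operator-swap mutation, and
one-point crossover, with single-individual elitism.  Fitness is the mean
cross-validation score over a *predefined* split plan; in adjusted mode
each estimator recovers the correct leakage-free residual target for the
split it is inside by matching the row set it was handed against the plan.

Two modes share the identical engine:

* adjusted — consumes a :class:`~resadj.preprocess.ResAdjDataset`; the
  residual-adjustment transformer refits feature residuals per split and
  the scorer reads the per-split residual-target columns.
* classic — consumes a raw table; the original target and metric (e.g.
  balanced accuracy for a multiclass ordinal outcome) are used unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import SelectPercentile, VarianceThreshold, f_classif, f_regression
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.metrics import balanced_accuracy_score, r2_score
from sklearn.preprocessing import MinMaxScaler, PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .preprocess import FULL, ResAdjDataset, SplitError, SplitPlan, identify_split
from .residualize import fit_residual_model, residuals
from .table import AdjustedTable, AdjustmentMap, FeatureSetCollection, TableError

ROLE_NAMES = (
    "FeatureSetSelector",
    "resAdjTransformer",
    "Selector",
    "Transformer",
    "Regressor",
    "Classifier",
)

SEARCH_END = "SEARCH_END"


class SearchFailure(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# templates


@dataclass(frozen=True)
class Template:
    steps: tuple[str, ...]

    def __post_init__(self) -> None:
        for s in self.steps:
            if s not in ROLE_NAMES:
                raise TableError(f"unknown template role {s!r}")
        if not self.steps or self.steps[-1] not in ("Regressor", "Classifier"):
            raise TableError("template must end with a Regressor or Classifier")
        if "FeatureSetSelector" in self.steps and self.steps[0] != "FeatureSetSelector":
            raise TableError("FeatureSetSelector must be the first template step")
        if "resAdjTransformer" in self.steps:
            pos = self.steps.index("resAdjTransformer")
            after_fss = self.steps[0] == "FeatureSetSelector" and pos == 1
            if pos != 0 and not after_fss:
                raise TableError(
                    "resAdjTransformer must be the first step or immediately "
                    "follow the FeatureSetSelector"
                )

    @classmethod
    def parse(cls, text: str) -> "Template":
        return cls(tuple(s.strip() for s in text.split("-") if s.strip()))

    @property
    def estimator_role(self) -> str:
        return self.steps[-1]

    def __str__(self) -> str:
        return "-".join(self.steps)


# ---------------------------------------------------------------------------
# operator pool


@dataclass(frozen=True)
class OperatorSpec:
    role: str
    name: str
    grid: tuple[tuple[str, tuple], ...]  # ((param, (values...)), ...)

    def param_names(self) -> list[str]:
        return [p for p, _ in self.grid]

    def values_of(self, param: str) -> tuple:
        for p, vals in self.grid:
            if p == param:
                return vals
        raise KeyError(param)


@dataclass
class OperatorPool:
    by_role: dict[str, list[OperatorSpec]]

    def operators(self, role: str) -> list[OperatorSpec]:
        ops = self.by_role.get(role, [])
        if not ops:
            raise TableError(f"operator pool has no operators for role {role!r}")
        return ops

    def spec(self, role: str, name: str) -> OperatorSpec:
        for op in self.operators(role):
            if op.name == name:
                return op
        raise KeyError((role, name))


def default_pool(set_names: list[str] | None = None) -> OperatorPool:
    """Compact deterministic pool: linear and tree estimators, variance /
    percentile selectors, scaling and polynomial transformers."""
    g = lambda **kw: tuple((k, tuple(v)) for k, v in kw.items())
    by_role: dict[str, list[OperatorSpec]] = {
        "resAdjTransformer": [OperatorSpec("resAdjTransformer", "resAdjTransformer", ())],
        "Selector": [
            OperatorSpec("Selector", "VarianceThreshold", g(threshold=[0.0, 0.05])),
            OperatorSpec("Selector", "SelectPercentile", g(percentile=[25, 50, 75, 100])),
        ],
        "Transformer": [
            OperatorSpec("Transformer", "StandardScaler", ()),
            OperatorSpec("Transformer", "MinMaxScaler", ()),
            OperatorSpec(
                "Transformer", "PolynomialFeatures", g(interaction_only=[True, False])
            ),
        ],
        "Regressor": [
            OperatorSpec("Regressor", "Ridge", g(alpha=[0.01, 0.1, 1.0, 10.0])),
            OperatorSpec("Regressor", "LinearRegression", ()),
            OperatorSpec("Regressor", "DecisionTreeRegressor", g(max_depth=[2, 3, 5])),
        ],
        "Classifier": [
            OperatorSpec("Classifier", "LogisticRegression", g(C=[0.01, 0.1, 1.0, 10.0])),
            OperatorSpec("Classifier", "DecisionTreeClassifier", g(max_depth=[2, 3, 5])),
        ],
    }
    if set_names:
        by_role["FeatureSetSelector"] = [
            OperatorSpec("FeatureSetSelector", "FeatureSetSelector", g(set_name=list(set_names)))
        ]
    return OperatorPool(by_role)


def _make_sklearn(name: str, params: dict, estimator_role: str):
    if name == "VarianceThreshold":
        return VarianceThreshold(**params)
    if name == "SelectPercentile":
        score_func = f_regression if estimator_role == "Regressor" else f_classif
        return SelectPercentile(score_func=score_func, **params)
    if name == "StandardScaler":
        return StandardScaler(**params)
    if name == "MinMaxScaler":
        return MinMaxScaler(**params)
    if name == "PolynomialFeatures":
        return PolynomialFeatures(degree=2, include_bias=False, **params)
    if name == "Ridge":
        return Ridge(**params)
    if name == "LinearRegression":
        return LinearRegression(**params)
    if name == "DecisionTreeRegressor":
        return DecisionTreeRegressor(random_state=0, **params)
    if name == "LogisticRegression":
        return LogisticRegression(max_iter=1000, **params)
    if name == "DecisionTreeClassifier":
        return DecisionTreeClassifier(random_state=0, **params)
    raise KeyError(name)


# ---------------------------------------------------------------------------
# individuals


@dataclass
class PipelineIndividual:
    """A configured pipeline: one (operator, hyperparameters) per template step."""

    steps: tuple[tuple[str, str, tuple[tuple[str, object], ...]], ...]
    # each step: (role, operator name, sorted (param, value) pairs)
    cv_score: float = float("-inf")
    creation_index: int = 0
    holdout_score: float | None = None

    @property
    def complexity(self) -> int:
        return len(self.steps)

    def key(self) -> tuple:
        return self.steps

    @property
    def selected_set(self) -> str | None:
        for role, _, params in self.steps:
            if role == "FeatureSetSelector":
                return dict(params)["set_name"]
        return None

    def describe(self) -> dict:
        return {
            "steps": [
                {"role": role, "operator": name, "params": dict(params)}
                for role, name, params in self.steps
            ],
            "cv_score": self.cv_score,
            "complexity": self.complexity,
            "holdout_score": self.holdout_score,
        }


# ---------------------------------------------------------------------------
# spec-level building blocks


def feature_set_select(
    table: AdjustedTable, collection: FeatureSetCollection, set_name: str
) -> AdjustedTable:
    """Restrict feature columns to the named set's members present in the
    table; all non-feature columns pass through untouched."""
    if set_name not in collection:
        raise TableError(f"unknown feature set {set_name!r}")
    members = set(collection.members(set_name))
    features = table.feature_names
    keep = [f for f in features if f in members]
    if not keep:
        raise TableError(
            f"feature set {set_name!r} has no members present in the table"
        )
    drop = [f for f in features if f not in members]
    return table.drop_columns(drop)


class ResAdjTransformerStep:
    """In-pipeline feature residualization.

    On fit, residual models for every mapped feature present in the input
    are fitted on the presented rows only; on transform, those models are
    applied and the covariate columns are dropped before the data flows on.
    Mapped features sharing a covariate list are residualized in one
    least-squares solve.
    """

    def __init__(self, amap: AdjustmentMap, covariate_columns: list[str]):
        self.amap = amap
        self.covariate_columns = list(covariate_columns)
        self.models_: dict | None = None
        self.used_covariates_: set[str] = set()

    def fit(self, df: pd.DataFrame, rows: np.ndarray, kinds: dict[str, str]) -> "ResAdjTransformerStep":
        self.models_ = {}
        present = set(df.columns)
        for name, covs in self.amap.entries:
            if name not in present:
                continue
            self.used_covariates_.update(covs)
            v = df[name].to_numpy(dtype=float)
            C = df[list(covs)].to_numpy(dtype=float) if covs else np.empty((len(df), 0))
            self.models_[name] = (
                fit_residual_model(
                    v, C, rows, kinds.get(name, "continuous"), covariate_names=covs
                ),
                list(covs),
            )
        return self

    def transform(self, df: pd.DataFrame, rows: np.ndarray) -> pd.DataFrame:
        if self.models_ is None:
            raise SearchFailure("resAdjTransformer.transform called before fit")
        out = df.iloc[rows].copy()
        local = np.arange(len(rows))
        for name, (model, covs) in self.models_.items():
            v = out[name].to_numpy(dtype=float)
            C = out[list(covs)].to_numpy(dtype=float) if covs else np.empty((len(out), 0))
            out[name] = residuals(model, v, C, local)
        # covariate columns never flow past this step, used in a model or not
        drop = [c for c in self.covariate_columns if c in out.columns]
        return out.drop(columns=drop)


def residual_scorer(
    resadj: ResAdjDataset, predictions: np.ndarray, presented_rows, metric: str = "r2"
) -> float:
    """Score predictions against the adjusted target of the split the
    presented rows belong to (or the full-fit residuals for a FULL match)."""
    split, _context = identify_split(resadj, presented_rows)
    y_true = resadj.adjusted_target(split, presented_rows)
    return score_predictions(y_true, np.asarray(predictions, dtype=float), metric)


def score_predictions(y_true, y_pred, metric: str) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if metric == "r2":
        return float(r2_score(y_true, y_pred))
    if metric == "neg_mse":
        return float(-np.mean((y_true - y_pred) ** 2))
    if metric == "balanced_accuracy":
        return float(balanced_accuracy_score(y_true, y_pred))
    raise TableError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# datasets the engine consumes


@dataclass
class ClassicDataset:
    """Unadjusted counterpart of ResAdjDataset: raw table, same plan shape."""

    table: AdjustedTable
    plan: SplitPlan
    holdout_table: AdjustedTable | None = None
    amap: AdjustmentMap | None = None  # features-only adjustment workflow

    @property
    def target_name(self) -> str:
        return self.table.target_name


def split_holdout(
    table: AdjustedTable, fraction: float, seed: int
) -> tuple[AdjustedTable, AdjustedTable]:
    """Seeded holdout split; identical row selection to the pre-processor's."""
    rng = np.random.default_rng(seed)
    m = table.m
    n_hold = int(round(m * fraction))
    perm = rng.permutation(m)
    hold = np.sort(perm[:n_hold])
    keep = np.sort(perm[n_hold:])
    return table.subset_rows(keep), table.subset_rows(hold)


# ---------------------------------------------------------------------------
# fitted pipelines


@dataclass
class FittedPipeline:
    """A pipeline fitted on a fixed row set, applicable to new rows.

    ``input_columns`` are the raw columns the pipeline expects (features
    plus, in adjusted mode, the covariates consumed by the residual step);
    ``used_columns`` are those that can influence predictions.
    """

    individual: PipelineIndividual
    mode: str  # "adjusted" | "classic"
    input_columns: list[str]
    used_columns: set[str]
    stages: list  # (kind, payload) in execution order
    estimator_role: str

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predict for the rows of ``df`` (must carry ``input_columns``)."""
        work = df[self.input_columns].copy()
        rows = np.arange(len(work))
        X = None
        for kind, payload in self.stages:
            if kind == "fss":
                work = work[payload]  # payload: surviving column list
            elif kind == "resadj":
                work = payload.transform(work, rows)
            elif kind == "sklearn":
                if X is None:
                    X = work.to_numpy(dtype=float)
                X = payload.transform(X)
            elif kind == "estimator":
                if X is None:
                    X = work.to_numpy(dtype=float)
                return payload.predict(X)
        raise SearchFailure("pipeline has no estimator stage")


def _fit_pipeline(
    ind: PipelineIndividual,
    data: ResAdjDataset | ClassicDataset,
    collection: FeatureSetCollection,
    fit_rows: np.ndarray,
    y_train: np.ndarray,
    estimator_role: str,
) -> FittedPipeline:
    mode = "adjusted" if isinstance(data, ResAdjDataset) else "classic"
    table = data.table
    feature_cols = table.feature_names
    has_resadj = any(role == "resAdjTransformer" for role, _, _ in ind.steps)
    input_columns = list(feature_cols)
    if has_resadj:
        input_columns += table.covariate_names
    work = table.df[input_columns].iloc[fit_rows]
    local_rows = np.arange(len(fit_rows))
    stages: list = []
    used: set[str] = set(feature_cols)
    X = None
    for role, name, params in ind.steps:
        p = dict(params)
        if role == "FeatureSetSelector":
            selected = feature_set_select(table, collection, p["set_name"]).feature_names
            keep = [c for c in work.columns if c in selected or c not in feature_cols]
            work = work[keep]
            used = set(selected)
            stages.append(("fss", keep))
        elif role == "resAdjTransformer":
            amap = getattr(data, "amap", None) or AdjustmentMap()
            step = ResAdjTransformerStep(amap, table.covariate_names)
            step.fit(work, local_rows, table.kinds)
            work = step.transform(work, local_rows)
            used |= step.used_covariates_
            stages.append(("resadj", step))
        elif role in ("Selector", "Transformer"):
            obj = _make_sklearn(name, p, estimator_role)
            if X is None:
                X = work.to_numpy(dtype=float)
            X = obj.fit_transform(X, y_train)
            stages.append(("sklearn", obj))
        elif role in ("Regressor", "Classifier"):
            obj = _make_sklearn(name, p, estimator_role)
            if X is None:
                X = work.to_numpy(dtype=float)
            obj.fit(X, y_train)
            stages.append(("estimator", obj))
        else:
            raise TableError(f"unknown role {role!r}")
    return FittedPipeline(ind, mode, input_columns, used, stages, estimator_role)


def _train_target(data, train_rows) -> np.ndarray:
    if isinstance(data, ResAdjDataset):
        split, context = identify_split(data, train_rows)
        if context != "fitting":
            raise SplitError("training rows matched a test set; CV plan mismatch")
        return data.adjusted_target(split, train_rows)
    return data.table.values(data.table.target_name)[np.asarray(train_rows, dtype=int)].astype(float)


def evaluate_individual(
    ind: PipelineIndividual,
    data: ResAdjDataset | ClassicDataset,
    collection: FeatureSetCollection,
    metric: str,
    estimator_role: str,
) -> float:
    """Mean CV score of one pipeline over the predefined split plan.

    Numeric failures inside an operator mark the pipeline invalid (score
    -inf); CV-plan mismatches are real errors and propagate.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    scores = []
    for train, test in data.plan.splits:
        y_train = _train_target(data, train)
        try:
            with warnings.catch_warnings():
                # an unconverged candidate is a legitimate (weak) pipeline
                warnings.simplefilter("ignore", ConvergenceWarning)
                fitted = _fit_pipeline(ind, data, collection, train, y_train, estimator_role)
                preds = fitted.predict(data.table.df.iloc[test][fitted.input_columns])
        except SplitError:
            raise
        except Exception:
            return float("-inf")
        if isinstance(data, ResAdjDataset):
            scores.append(residual_scorer(data, preds, test, metric))
        else:
            y_test = data.table.values(data.table.target_name)[test].astype(float)
            scores.append(score_predictions(y_test, preds, metric))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# the genetic program


def _random_individual(template: Template, pool: OperatorPool, rng, counter) -> PipelineIndividual:
    steps = []
    for role in template.steps:
        ops = pool.operators(role)
        op = ops[rng.integers(len(ops))]
        params = tuple(
            sorted((p, vals[rng.integers(len(vals))]) for p, vals in op.grid)
        )
        steps.append((role, op.name, params))
    return PipelineIndividual(tuple(steps), creation_index=next(counter))


def _mutate(ind: PipelineIndividual, pool: OperatorPool, rng, counter) -> PipelineIndividual:
    steps = list(ind.steps)
    idx = int(rng.integers(len(steps)))
    role, name, params = steps[idx]
    ops = pool.operators(role)
    swap = rng.random() < 0.5 and len(ops) > 1
    if swap or not params:
        choices = [op for op in ops if op.name != name] or ops
        op = choices[rng.integers(len(choices))]
        new_params = tuple(
            sorted((p, vals[rng.integers(len(vals))]) for p, vals in op.grid)
        )
        steps[idx] = (role, op.name, new_params)
    else:
        op = pool.spec(role, name)
        pnames = op.param_names()
        pname = pnames[rng.integers(len(pnames))]
        vals = op.values_of(pname)
        new_val = vals[rng.integers(len(vals))]
        steps[idx] = (role, name, tuple(
            sorted((p, new_val if p == pname else v) for p, v in params)
        ))
    return PipelineIndividual(tuple(steps), creation_index=next(counter))


def _crossover(a: PipelineIndividual, b: PipelineIndividual, rng, counter) -> PipelineIndividual:
    if len(a.steps) < 2:
        return PipelineIndividual(a.steps, creation_index=next(counter))
    point = int(rng.integers(1, len(a.steps)))
    return PipelineIndividual(
        a.steps[:point] + b.steps[point:], creation_index=next(counter)
    )


def _dominates(a: PipelineIndividual, b: PipelineIndividual) -> bool:
    ge = a.cv_score >= b.cv_score and a.complexity <= b.complexity
    strict = a.cv_score > b.cv_score or a.complexity < b.complexity
    return ge and strict


def _tournament(pop, rng) -> PipelineIndividual:
    i, j = rng.integers(len(pop)), rng.integers(len(pop))
    a, b = pop[i], pop[j]
    if _dominates(a, b):
        return a
    if _dominates(b, a):
        return b
    return a if (a.cv_score, -a.creation_index) >= (b.cv_score, -b.creation_index) else b


def _best(pop) -> PipelineIndividual:
    # highest score; ties -> lower complexity, then earlier creation
    return max(pop, key=lambda x: (x.cv_score, -x.complexity, -x.creation_index))


def evolve(
    data: ResAdjDataset | ClassicDataset,
    template: Template | str,
    pool: OperatorPool | None,
    collection: FeatureSetCollection,
    population: int = 20,
    generations: int = 5,
    metric: str = "r2",
    seed: int = 0,
    mutation_rate: float = 0.9,
    crossover_rate: float = 0.1,
) -> tuple[PipelineIndividual, list[dict], FittedPipeline]:
    """Run the seeded GP search; returns (best individual, generation log,
    best pipeline refit on all non-holdout rows).

    Selection is two-objective (maximize CV score, minimize step count);
    the reported winner is the highest-scoring individual, ties broken by
    lower complexity then earlier creation.  Identical (pipeline, plan)
    evaluations are memoized within the run.
    """
    if population < 1:
        raise TableError("population must be >= 1")
    if generations < 0:
        raise TableError("generations must be >= 0")
    if isinstance(template, str):
        template = Template.parse(template)
    if pool is None:
        pool = default_pool(collection.names())
    if "FeatureSetSelector" in template.steps and "FeatureSetSelector" not in pool.by_role:
        pool.by_role["FeatureSetSelector"] = default_pool(collection.names()).by_role[
            "FeatureSetSelector"
        ]
    estimator_role = template.estimator_role
    rng = np.random.default_rng(seed)
    counter = itertools.count()
    cache: dict[tuple, float] = {}

    def score(ind: PipelineIndividual) -> None:
        k = ind.key()
        if k not in cache:
            cache[k] = evaluate_individual(ind, data, collection, metric, estimator_role)
        ind.cv_score = cache[k]

    pop = [_random_individual(template, pool, rng, counter) for _ in range(population)]
    log: list[dict] = []

    def log_generation(gen: int) -> None:
        finite = [p.cv_score for p in pop if np.isfinite(p.cv_score)]
        if not finite:
            raise SearchFailure(
                f"generation {gen}: every pipeline in the population is invalid"
            )
        log.append(
            {
                "generation": gen,
                "best_score": max(finite),
                "mean_score": float(np.mean(finite)),
                "n_invalid": population - len(finite),
                "best_pipeline": str(_best(pop).steps),
            }
        )

    for ind in pop:
        score(ind)
    log_generation(0)

    for gen in range(1, generations + 1):
        new_pop = [_best(pop)]  # elitism keeps the incumbent
        while len(new_pop) < population:
            r = rng.random()
            if r < crossover_rate and population >= 2:
                child = _crossover(_tournament(pop, rng), _tournament(pop, rng), rng, counter)
            elif r < crossover_rate + mutation_rate:
                child = _mutate(_tournament(pop, rng), pool, rng, counter)
            else:
                child = PipelineIndividual(
                    _tournament(pop, rng).steps, creation_index=next(counter)
                )
            new_pop.append(child)
        pop = new_pop
        for ind in pop:
            score(ind)
        log_generation(gen)

    best = _best(pop)
    if isinstance(data, ResAdjDataset):
        data.call_log.append((SEARCH_END, None))
    # final refit on all non-holdout rows (the FULL context)
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    all_rows = np.arange(data.table.m)
    y_full = _train_target(data, all_rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fitted = _fit_pipeline(best, data, collection, all_rows, y_full, estimator_role)
    return best, log, fitted


def holdout_score(
    fitted: FittedPipeline, data: ResAdjDataset | ClassicDataset, metric: str
) -> float:
    """Score the refit pipeline on the holdout rows.

    Adjusted mode scores against the holdout target residualized by the
    whole-training-input covariate model; classic mode against the raw
    target.
    """
    if data.holdout_table is None:
        raise TableError("dataset has no holdout set")
    df = data.holdout_table.df[fitted.input_columns]
    preds = fitted.predict(df)
    if isinstance(data, ResAdjDataset):
        y_true = data.holdout_residual
    else:
        y_true = data.holdout_table.values(data.holdout_table.target_name).astype(float)
    score = score_predictions(y_true, preds, metric)
    fitted.individual.holdout_score = score
    return score
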