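"""Leakage-free residualization: regressing covariates out of a variable.

Adjusting a variable *v* for covariates means fitting a predictor of *v*
from the covariates and replacing *v* by its residuals.  Inside
cross-validation this is only sound if the predictor is fitted on the
training rows of the current split and then *applied* to all rows — fitting
on the full data leaks test-row information into training.  This module
implements exactly that primitive:

* continuous *v*: ordinary least squares with intercept; residual
  r_i = v_i - yhat_i.
* binary / multiclass-ordinal *v*: multinomial logistic regression with
  intercept; residual r_i = v_i - sum_k class_value_k * phat_ik
  (observed value minus the probability-weighted class value).

A small ridge penalty (1e-4 on coefficients, never the intercept) keeps the
logistic fit convergent under separation, which is routine in small CV
folds.  Continuous fits use the minimum-norm least-squares solution so
collinear (e.g. encoded) covariates never raise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .table import AdjustedTable, AdjustmentMap

#: inverse of the ridge strength applied to categorical residual fits
_LOGISTIC_C = 1e4


class ResidualError(ValueError):
    pass


@dataclass
class ResidualModel:
    """A covariate model for one variable, fitted on designated rows only."""

    variable_kind: str  # continuous | binary | ordinal
    covariate_names: list[str]
    fit_rows: np.ndarray
    coef: np.ndarray | None = None  # continuous: [intercept, slopes...]
    classifier: LogisticRegression | None = None
    class_values: np.ndarray | None = None  # categorical: ordered numeric levels
    constant_class: float | None = field(default=None)  # single-class fold

    def predict(self, C: np.ndarray) -> np.ndarray:
        """Expected value of the variable given covariates ``C`` (rows x p)."""
        C = np.asarray(C, dtype=float)
        if self.variable_kind == "continuous":
            design = np.column_stack([np.ones(len(C)), C])
            return design @ self.coef
        if self.constant_class is not None:
            return np.full(len(C), self.constant_class)
        probs = self.classifier.predict_proba(C)
        return probs @ self.class_values


def fit_residual_model(
    v: np.ndarray, C: np.ndarray, rows, kind: str, covariate_names=None
) -> ResidualModel:
    """Fit the covariate model for ``v`` using only rows in ``rows``.

    ``C`` may have zero columns, in which case the model is intercept-only
    (continuous) or the empirical class distribution (categorical).
    """
    rows = np.asarray(rows, dtype=int)
    if rows.size == 0:
        raise ResidualError("cannot fit a residual model on an empty row set")
    if kind not in ("continuous", "binary", "ordinal"):
        raise ResidualError(f"cannot residualize a variable of kind {kind!r}")
    v = np.asarray(v, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C.reshape(-1, 1)
    names = list(covariate_names) if covariate_names is not None else [
        f"c{j}" for j in range(C.shape[1])
    ]
    v_tr, C_tr = v[rows], C[rows]

    if kind == "continuous":
        design = np.column_stack([np.ones(len(rows)), C_tr])
        coef, *_ = np.linalg.lstsq(design, v_tr, rcond=None)
        return ResidualModel("continuous", names, rows, coef=coef)

    classes = np.unique(v_tr)
    if kind == "binary" and classes.size > 2:
        raise ResidualError(
            f"binary variable has {classes.size} observed levels on training rows"
        )
    if classes.size == 1:
        # degenerate fold: the predicted class probability is identically 1
        return ResidualModel(
            kind, names, rows, class_values=classes, constant_class=float(classes[0])
        )
    zero_covariates = C_tr.shape[1] == 0
    if zero_covariates:
        # intercept-only classifier: empirical class distribution
        C_tr = np.zeros((len(rows), 1))
    clf = LogisticRegression(C=_LOGISTIC_C, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(C_tr, v_tr)
    model = ResidualModel(kind, names, rows, classifier=clf, class_values=classes)
    if zero_covariates:
        # prediction must see the same dummy column
        model._zero_covariates = True  # type: ignore[attr-defined]
    return model


def residuals(model: ResidualModel, v: np.ndarray, C: np.ndarray, rows) -> np.ndarray:
    """Residuals of ``v`` under ``model`` over ``rows`` (which may extend
    beyond the rows the model was fitted on — that is the point)."""
    rows = np.asarray(rows, dtype=int)
    v = np.asarray(v, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C.reshape(-1, 1)
    expected_p = len(model.covariate_names)
    if C.shape[1] != expected_p:
        raise ResidualError(
            f"covariate matrix has {C.shape[1]} columns; model expects {expected_p}"
        )
    C_rows = C[rows]
    if getattr(model, "_zero_covariates", False):
        C_rows = np.zeros((len(rows), 1))
    return v[rows] - model.predict(C_rows)


def adjust_for_split(
    table: AdjustedTable,
    amap: AdjustmentMap,
    train_rows,
    test_rows,
    include_target: bool = False,
):
    """Residualize every mapped column for one CV split.

    Models are fitted on ``train_rows`` only and applied over
    ``train_rows + test_rows``.  Returns ``(adjusted, models)`` where
    ``adjusted`` maps column name -> residual vector aligned to
    train-then-test row order, and ``models`` maps column name -> the
    fitted :class:`ResidualModel`.  Unmapped columns are untouched;
    covariate columns are never modified here.
    """
    train_rows = np.asarray(train_rows, dtype=int)
    test_rows = np.asarray(test_rows, dtype=int)
    rows = np.concatenate([train_rows, test_rows])
    adjusted: dict[str, np.ndarray] = {}
    models: dict[str, ResidualModel] = {}

    targets = list(amap.entries)
    if include_target and amap.adjust_target:
        tname = table.target_name
        if tname is None:
            raise ResidualError("adjust_target set but table has no target column")
        targets = targets + [(tname, amap.target_covariates)]

    for name, covs in targets:
        v = table.values(name).astype(float)
        C = table.df[covs].to_numpy(dtype=float) if covs else np.empty((table.m, 0))
        kind = table.kind_of(name)
        model = fit_residual_model(v, C, train_rows, kind, covariate_names=covs)
        adjusted[name] = residuals(model, v, C, rows)
        models[name] = model
    return adjusted, models
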