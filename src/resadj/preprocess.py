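"""Predefined CV splits and leakage-free target residuals as table columns.

The pipeline search cannot ask an estimator "which split are you in?" —
estimators only see the rows they are handed.  The pre-processor therefore
materializes everything split-dependent *into the table*: for each split i
an indicator column (1 = train, 0 = test, -1 = row not in the split) and a
residual-target column holding the no-leakage residuals of y computed from
a covariate model fitted on that split's training rows only.  One further
column carries residuals from a whole-input fit, used exclusively for the
final refit/report after the search has ended.  Downstream components
recover their split by matching the row set they were handed against the
plan (:func:`identify_split`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .residualize import adjust_for_split, fit_residual_model, residuals
from .table import (
    FULL_RESIDUAL,
    INDICATOR_FMT,
    RESIDUAL_FMT,
    AdjustedTable,
    AdjustmentMap,
    TableError,
)

FULL = "FULL"


class SplitError(ValueError):
    pass


@dataclass
class SplitPlan:
    """Predefined train/test row partitions, reproducible from a seed."""

    splits: list[tuple[np.ndarray, np.ndarray]]
    train_fraction: float
    scheme: str  # "shuffle" | "kfold"
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.splits)

    def validate(self, m: int) -> None:
        for i, (train, test) in enumerate(self.splits):
            if len(train) == 0 or len(test) == 0:
                raise SplitError(f"split {i} has an empty train or test set")
            if set(train) & set(test):
                raise SplitError(f"split {i} train and test sets overlap")
            if max(train.max(), test.max()) >= m or min(train.min(), test.min()) < 0:
                raise SplitError(f"split {i} references rows outside 0..{m - 1}")


def make_split_plan(
    m: int,
    n_splits: int,
    scheme: str = "shuffle",
    train_fraction: float = 0.75,
    seed: int = 0,
) -> SplitPlan:
    """Draw a reproducible split plan over ``m`` rows.

    ``shuffle`` draws ``n_splits`` independent train/test partitions at
    ``train_fraction``; ``kfold`` partitions the rows into ``n_splits``
    folds, each serving once as the test set.
    """
    if n_splits < 2:
        raise SplitError("n_splits must be >= 2")
    if n_splits > m:
        raise SplitError(f"n_splits={n_splits} exceeds sample count m={m}")
    rng = np.random.default_rng(seed)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme == "shuffle":
        if not 0 < train_fraction < 1:
            raise SplitError("train_fraction must lie strictly between 0 and 1")
        n_train = int(round(m * train_fraction))
        n_train = min(max(n_train, 1), m - 1)
        for _ in range(n_splits):
            perm = rng.permutation(m)
            splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    elif scheme == "kfold":
        perm = rng.permutation(m)
        folds = np.array_split(perm, n_splits)
        for i in range(n_splits):
            test = np.sort(folds[i])
            train = np.sort(np.concatenate([folds[j] for j in range(n_splits) if j != i]))
            splits.append((train, test))
    else:
        raise SplitError(f"unknown scheme {scheme!r}")
    plan = SplitPlan(splits, train_fraction, scheme, seed)
    plan.validate(m)
    return plan


@dataclass
class ResAdjDataset:
    """The augmented table the pipeline search consumes.

    ``table`` rows are the non-holdout samples, re-indexed 0..m-1; the
    holdout (if any) is kept separately with its target already residualized
    by a model fitted on all non-holdout rows.  ``call_log`` records every
    split lookup — the no-leakage invariant is that no FULL lookup happens
    while a search is still inside CV.
    """

    table: AdjustedTable
    plan: SplitPlan
    amap: AdjustmentMap
    target_name: str
    target_kind: str
    holdout_table: AdjustedTable | None = None
    holdout_residual: np.ndarray | None = None
    call_log: list = field(default_factory=list)

    def indicator_column(self, i: int) -> str:
        return INDICATOR_FMT.format(i=i)

    def residual_column(self, i: int) -> str:
        return RESIDUAL_FMT.format(i=i)

    def adjusted_target(self, split, rows) -> np.ndarray:
        """The correct adjusted-target values for ``rows`` under ``split``
        (a split index or FULL)."""
        col = FULL_RESIDUAL if split == FULL else self.residual_column(split)
        return self.table.df[col].to_numpy()[np.asarray(rows, dtype=int)]


def build_resadj_dataset(
    table: AdjustedTable,
    amap: AdjustmentMap,
    plan: SplitPlan,
    holdout_fraction: float | None = None,
    seed: int = 0,
) -> ResAdjDataset:
    """Materialize indicator and residual-target columns for every split.

    Holdout rows (if requested) are removed first and never touch any
    fitted model; the plan's row indices refer to the remaining rows.
    Feature adjustments are *not* applied here — they happen in-pipeline,
    per split, inside the residual-adjustment transformer.
    """
    if not amap.adjust_target:
        raise TableError(
            "adjustment map does not adjust the target; use the features-only "
            "workflow (resAdjTransformer inside a classic search) instead"
        )
    tname = table.target_name
    if tname is None:
        raise TableError("table has no target column")
    tkind = table.kind_of(tname)
    if tkind not in ("continuous", "binary", "ordinal"):
        raise TableError(f"target kind {tkind!r} cannot be residualized")
    amap.validate(table)

    m_all = table.m
    holdout_table = None
    if holdout_fraction:
        if not 0 < holdout_fraction < 1:
            raise SplitError("holdout_fraction must lie strictly between 0 and 1")
        rng = np.random.default_rng(seed)
        n_hold = int(round(m_all * holdout_fraction))
        perm = rng.permutation(m_all)
        hold_rows = np.sort(perm[:n_hold])
        keep_rows = np.sort(perm[n_hold:])
        holdout_table = table.subset_rows(hold_rows)
        work = table.subset_rows(keep_rows)
    else:
        work = table.copy()
    m = work.m
    plan.validate(m)

    covs = amap.target_covariates
    v = work.values(tname).astype(float)
    C = work.df[covs].to_numpy(dtype=float) if covs else np.empty((m, 0))

    aug = work
    for i, (train, test) in enumerate(plan.splits):
        indicator = np.full(m, -1, dtype=int)
        indicator[train] = 1
        indicator[test] = 0
        model = fit_residual_model(v, C, train, tkind, covariate_names=covs)
        resid = np.full(m, np.nan)
        in_split = np.concatenate([train, test])
        resid[in_split] = residuals(model, v, C, in_split)
        aug = aug.with_column(
            INDICATOR_FMT.format(i=i), indicator, "indicator", "ordinal"
        )
        aug = aug.with_column(
            RESIDUAL_FMT.format(i=i), resid, "residual_target", "continuous"
        )

    all_rows = np.arange(m)
    full_model = fit_residual_model(v, C, all_rows, tkind, covariate_names=covs)
    aug = aug.with_column(
        FULL_RESIDUAL,
        residuals(full_model, v, C, all_rows),
        "residual_target",
        "continuous",
    )

    holdout_residual = None
    if holdout_table is not None:
        hv = holdout_table.values(tname).astype(float)
        hC = (
            holdout_table.df[covs].to_numpy(dtype=float)
            if covs
            else np.empty((holdout_table.m, 0))
        )
        holdout_residual = residuals(
            full_model, hv, hC, np.arange(holdout_table.m)
        )

    return ResAdjDataset(
        table=aug,
        plan=plan,
        amap=amap,
        target_name=tname,
        target_kind=tkind,
        holdout_table=holdout_table,
        holdout_residual=holdout_residual,
    )


def identify_split(resadj: ResAdjDataset, presented_rows) -> tuple:
    """Map a presented row set to its split.

    Returns ``(i, "fitting")`` when the rows equal split i's train set,
    ``(i, "scoring")`` for its test set, or ``(FULL, "fitting")`` when the
    rows are all non-holdout rows.  Anything else is an ambiguity error —
    a silent wrong-target pick is the worst possible failure mode, so exact
    set equality is required.
    """
    rows = frozenset(int(r) for r in np.asarray(presented_rows).ravel())
    if not rows:
        raise SplitError("presented row set is empty")
    matches = []
    if rows == frozenset(range(resadj.table.m)):
        matches.append((FULL, "fitting"))
    for i, (train, test) in enumerate(resadj.plan.splits):
        if rows == frozenset(train.tolist()):
            matches.append((i, "fitting"))
        if rows == frozenset(test.tolist()):
            matches.append((i, "scoring"))
    if len(matches) != 1:
        raise SplitError(
            f"presented rows match {len(matches)} splits "
            "(expected exactly one); the CV plan does not agree with the data"
        )
    resadj.call_log.append(matches[0])
    return matches[0]
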