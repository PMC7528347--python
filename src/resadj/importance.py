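"""Permutation importance of input columns, and cross-run aggregation.

A column's importance for a fitted pipeline is the mean drop in holdout
score when that column alone is shuffled across the holdout rows.  Because
independent pipeline-search runs select different pipelines of different
quality, per-run percentages are combined by a testing-score-weighted
average: runs with better holdout scores count more, and runs whose
holdout score is non-positive are excluded (their percentage base is
meaningless) but counted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .search import FittedPipeline, score_predictions


class ImportanceError(ValueError):
    pass


@dataclass
class ImportanceRecord:
    """Per-run permutation-importance result on the holdout rows."""

    run_id: str
    testing_score: float
    decreases: dict[str, float]
    n_repeats: int
    seed: int


def permutation_importance(
    fitted: FittedPipeline,
    holdout_df: pd.DataFrame,
    y_true: np.ndarray,
    metric: str,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Mean score decrease per input column over ``n_repeats`` shuffles.

    Columns the pipeline provably never uses (outside its selected feature
    set and its residual models' covariates) are reported as exactly 0
    without recomputation — shuffling them cannot alter predictions.
    Negative decreases are retained, not clipped.
    """
    if n_repeats < 1:
        raise ImportanceError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    df = holdout_df[fitted.input_columns]
    y_true = np.asarray(y_true, dtype=float)
    base = score_predictions(y_true, fitted.predict(df), metric)
    decreases: dict[str, float] = {}
    n = len(df)
    for col in fitted.input_columns:
        if col not in fitted.used_columns:
            decreases[col] = 0.0
            continue
        scores = np.empty(n_repeats)
        for rep in range(n_repeats):
            permuted = df.copy()
            permuted[col] = permuted[col].to_numpy()[rng.permutation(n)]
            scores[rep] = score_predictions(y_true, fitted.predict(permuted), metric)
        decreases[col] = float(base - scores.mean())
    return decreases


def aggregate_importance(
    records: list[ImportanceRecord],
) -> tuple[dict[str, float], dict]:
    """Score-weighted average of per-run mean score decreases, expressed as
    a percentage of each run's own testing score.

    For each column: sum_r w_r * (100 * decrease_r / score_r) / sum_r w_r
    with w_r the run's testing score.  Runs with testing score <= 0 are
    excluded and counted in the returned report.  A column absent from a
    run's record contributes decrease 0 for that run.
    """
    if not records:
        raise ImportanceError("no importance records to aggregate")
    included = [r for r in records if r.testing_score > 0]
    excluded = len(records) - len(included)
    if not included:
        raise ImportanceError("all runs have testing score <= 0; nothing to aggregate")
    columns: list[str] = []
    for r in included:
        for c in r.decreases:
            if c not in columns:
                columns.append(c)
    total_w = sum(r.testing_score for r in included)
    weighted: dict[str, float] = {}
    for col in columns:
        acc = 0.0
        for r in included:
            pct = 100.0 * r.decreases.get(col, 0.0) / r.testing_score
            acc += r.testing_score * pct
        weighted[col] = acc / total_w
    report = {"n_runs": len(records), "n_included": len(included), "n_excluded": excluded}
    return weighted, report


def importance_table(weighted: dict[str, float], report: dict) -> pd.DataFrame:
    """Tidy frame sorted by weighted percentage, ready for CSV output."""
    df = pd.DataFrame(
        {"column": list(weighted), "weighted_pct": list(weighted.values())}
    ).sort_values("weighted_pct", ascending=False, kind="stable")
    df["n_runs_included"] = report["n_included"]
    return df.reset_index(drop=True)


def plot_importance(weighted: dict[str, float], top_k: int = 20, ax=None):
    """Horizontal bar plot of the top-k columns (cosmetic extra)."""
    import matplotlib.pyplot as plt

    items = sorted(weighted.items(), key=lambda kv: kv[1], reverse=True)[:top_k]
    names = [k for k, _ in items][::-1]
    vals = [v for _, v in items][::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(items) + 1))
    ax.barh(names, vals)
    ax.set_xlabel("weighted mean score decrease (% of testing score)")
    return ax
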