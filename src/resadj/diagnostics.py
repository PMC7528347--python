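"""Covariate-relevance diagnostics: Dunn-index k-means sweep and the
Biological Homogeneity Index (BHI).

Before deciding which covariates to adjust for, it helps to ask whether the
samples cluster along those covariates at all.  The procedure: sweep k-means
over a k range, keep the clustering maximizing the Dunn index (minimum
intercluster distance over maximum intracluster diameter), then compute the
BHI of that clustering against each candidate annotation — the average,
over clusters, of the fraction of within-cluster sample pairs sharing the
annotation.  A BHI near 1 says the clustering is organized by that
annotation (adjust for it); near the chance level says it is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans


class DiagnosticsError(ValueError):
    pass


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray
    dunn: float
    seed: int


def dunn_index(points: np.ndarray, labels) -> float:
    """Minimum intercluster distance divided by maximum intracluster
    diameter (Euclidean).

    All-singleton clusterings have zero diameter and return +inf (with a
    warning); the fully degenerate 0/0 case (all points identical) returns
    0 — no separation evidence.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points.reshape(-1, 1)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DiagnosticsError("Dunn index requires at least 2 clusters")
    groups = [points[labels == u] for u in uniq]
    min_between = min(
        cdist(groups[i], groups[j]).min()
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    )
    diameters = [pdist(g).max() if len(g) > 1 else 0.0 for g in groups]
    max_within = max(diameters)
    if max_within == 0.0:
        if min_between == 0.0:
            return 0.0
        warnings.warn("all clusters are singletons or zero-diameter; Dunn = +inf")
        return float("inf")
    return float(min_between / max_within)


def kmeans_sweep(
    points: np.ndarray,
    k_min: int,
    k_max: int,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[ClusteringResult, pd.DataFrame]:
    """Seeded k-means for each k in [k_min, k_max]; keep the clustering with
    the highest Dunn index (ties -> smaller k).  Returns the winner and the
    per-k Dunn table."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points.reshape(-1, 1)
    m = len(points)
    if k_min < 2:
        raise DiagnosticsError("k_min must be >= 2")
    if k_max > m - 1:
        raise DiagnosticsError(f"k_max={k_max} must be <= m-1={m - 1}")
    if k_min > k_max:
        raise DiagnosticsError("k_min must be <= k_max")
    rows = []
    best: ClusteringResult | None = None
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(points)
        d = dunn_index(points, labels)
        rows.append({"k": k, "dunn": d, "inertia": float(km.inertia_)})
        if best is None or d > best.dunn:
            best = ClusteringResult(k=k, labels=labels, dunn=d, seed=seed)
    return best, pd.DataFrame(rows)


def bhi(labels, annotations, weighting: str = "cluster") -> float:
    """Homogeneity of a clustering with respect to a sample annotation.

    Per cluster with >= 2 members: the proportion of unordered member pairs
    with identical annotation.  ``weighting="cluster"`` (default) averages
    these proportions unweighted over qualifying clusters; ``"pair"`` pools
    all qualifying pairs.  Clusters with < 2 members are skipped.
    """
    labels = np.asarray(labels)
    annotations = np.asarray(annotations)
    if labels.shape != annotations.shape:
        raise DiagnosticsError("labels and annotations must be aligned")
    props: list[float] = []
    same_total = 0
    pair_total = 0
    for u in np.unique(labels):
        ann = annotations[labels == u]
        n = len(ann)
        if n < 2:
            continue
        pairs = n * (n - 1) // 2
        same = sum(
            int(ann[i] == ann[j]) for i in range(n) for j in range(i + 1, n)
        )
        props.append(same / pairs)
        same_total += same
        pair_total += pairs
    if not props:
        raise DiagnosticsError("no cluster has >= 2 members; BHI undefined")
    if weighting == "pair":
        return same_total / pair_total
    if weighting != "cluster":
        raise DiagnosticsError(f"unknown weighting {weighting!r}")
    return float(np.mean(props))
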