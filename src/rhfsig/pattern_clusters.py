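"""Expression-pattern clustering of DEG sets across conditions.

Per-gene condition means are row-standardized (z = (x - mean) / sd) and
partitioned by k-means.  For row-standardized vectors over n conditions the
squared Euclidean distance equals 2(n-1)(1 - Pearson r), so Lloyd iterations
on z-scored rows realize one-minus-Pearson-correlation clustering.  Cluster
ids are canonicalized (descending size, then lexicographically smallest
member) so assignments are comparable across runs.  A secretome annotation
step tags cluster members encoding secreted factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class ZScoreMatrix:
    """Row-standardized condition means plus the excluded constant rows."""

    z: pd.DataFrame
    dropped_constant: list[str]


@dataclass
class ClusterAssignment:
    labels: pd.Series          # gene -> cluster id in 1..k
    k: int
    centroids: pd.DataFrame    # cluster id -> mean z profile
    seed: int
    inertia: float


def zscore_rows(means: pd.DataFrame) -> ZScoreMatrix:
    """Standardize each row to mean 0 / sample sd 1.

    Rows with zero variance cannot be standardized; they are excluded from
    the result and reported in ``dropped_constant``.
    """
    if means.shape[1] < 2:
        raise ValueError("need at least 2 conditions to z-score")
    arr = means.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    constant = sd == 0
    z = (arr - arr.mean(axis=1, keepdims=True)) / np.where(constant, 1.0, sd)[:, None]
    out = pd.DataFrame(z[~constant], index=means.index[~constant],
                       columns=means.columns)
    return ZScoreMatrix(z=out, dropped_constant=list(means.index[constant]))


def kmeans_patterns(z: ZScoreMatrix | pd.DataFrame, k: int, seed: int,
                    n_restarts: int = 10) -> ClusterAssignment:
    """k-means over z-scored rows, best of ``n_restarts`` k-means++ starts.

    Rows are sorted canonically by gene id before fitting so the assignment
    (up to the canonical relabeling applied afterwards) does not depend on
    input row order.
    """
    zdf = z.z if isinstance(z, ZScoreMatrix) else z
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > zdf.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes ({zdf.shape[0]})")
    zdf = zdf.sort_index(kind="stable")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(zdf.to_numpy(dtype=float))
    labels = pd.Series(raw, index=zdf.index)

    # canonical ids: descending cluster size, ties by smallest member id
    order = sorted(
        range(k),
        key=lambda c: (-int((labels == c).sum()), min(labels.index[labels == c])),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = labels.map(remap)

    centroids = (
        zdf.groupby(labels).mean().sort_index()
    )
    centroids.index.name = "cluster"
    return ClusterAssignment(labels=labels, k=k, centroids=centroids,
                             seed=seed, inertia=float(km.inertia_))


def cluster_profile_table(assign: ClusterAssignment,
                          z: ZScoreMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-cluster mean z profile and member count.

    The returned table has one row per cluster id with the centroid profile
    (arithmetic mean over member rows) and a ``size`` column.
    """
    zdf = z.z if isinstance(z, ZScoreMatrix) else z
    missing = set(zdf.index) - set(assign.labels.index)
    if missing:
        raise ValueError(f"assignment does not cover {len(missing)} rows")
    profiles = zdf.groupby(assign.labels.reindex(zdf.index)).mean()
    profiles["size"] = assign.labels.reindex(zdf.index).value_counts().sort_index()
    profiles.index.name = "cluster"
    return profiles


def tag_secreted(genes: set[str], secretome: set[str],
                 labels: pd.Series | None = None) -> dict:
    """Intersect a gene set with a secretome annotation.

    Returns the tagged subset and, if a cluster assignment is supplied,
    per-cluster counts of secreted members.
    """
    if not secretome:
        warnings.warn("empty secretome annotation; nothing can be tagged")
        return {"secreted": set(), "per_cluster": {}}
    tagged = set(genes) & set(secretome)
    per_cluster: dict[int, int] = {}
    if labels is not None:
        hit = labels[labels.index.isin(tagged)]
        per_cluster = hit.value_counts().sort_index().to_dict()
    return {"secreted": tagged, "per_cluster": per_cluster}
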