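"""Clustering of the topological chemical space.

Compounds are grouped in the (Estrada, Wiener, Gutman) index space —
optionally with the enthalpy as a fourth variable — using K-Means
(k-means++ seeding, Lloyd iterations, one initialization by default) with
an elbow scan over k, a DBSCAN comparison, and validity scoring by the
mean silhouette coefficient and the Davies–Bouldin score.

Index features are z-scored before clustering by default: the Gutman
index is orders of magnitude larger than the Estrada index and would
otherwise dominate Euclidean distances.  Raw-space clustering is available
with ``scale=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans
from sklearn.metrics import (
    davies_bouldin_score,
    silhouette_samples,
    silhouette_score,
)

from .errors import UndefinedValidityError
from .selection import zscore


def prepare_features(
    table: pd.DataFrame,
    columns=("estrada", "wiener", "gutman"),
    scale: bool = True,
) -> np.ndarray:
    """Extract and (by default) z-score the clustering variables."""
    X = table[list(columns)].to_numpy(dtype=float)
    return zscore(X).apply(X) if scale else X


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    iterations: int
    seed: int
    k: int = field(init=False)

    def __post_init__(self):
        self.k = self.centroids.shape[0]


def kmeans(X, k: int, n_init: int = 1, seed: int = 0, max_iter: int = 300) -> KMeansResult:
    """K-Means with k-means++ seeding and Lloyd iterations.

    ``n_init`` runs are performed and the lowest-inertia run kept (one
    initialization by default, matching the clustering protocol used for
    the index space).
    """
    X = np.asarray(X, dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    est = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    return KMeansResult(
        labels=est.labels_.copy(),
        centroids=est.cluster_centers_.copy(),
        inertia=float(est.inertia_),
        iterations=int(est.n_iter_),
        seed=seed,
    )


def elbow(X, k_range, n_init: int = 1, seed: int = 0) -> pd.DataFrame:
    """Inertia (sum of squared distances to the nearest centroid) per k."""
    rows = [
        {"k": int(k), "inertia": kmeans(X, int(k), n_init=n_init, seed=seed).inertia}
        for k in k_range
    ]
    return pd.DataFrame(rows)


def dbscan(X, eps: float = 0.1, min_samples: int = 20) -> np.ndarray:
    """Density-based labels (Euclidean metric); noise labelled −1."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    return DBSCAN(eps=eps, min_samples=min_samples, metric="euclidean").fit_predict(
        np.asarray(X, dtype=float)
    )


@dataclass
class ClusterValidity:
    mean_silhouette: float
    silhouettes: np.ndarray
    davies_bouldin: float

    def as_dict(self) -> dict:
        return {
            "mean_silhouette": self.mean_silhouette,
            "davies_bouldin": self.davies_bouldin,
        }


def validity(X, labels) -> ClusterValidity:
    """Mean/per-sample silhouette and Davies–Bouldin score.

    Noise points (label −1) are excluded; at least two non-noise clusters
    are required, otherwise :class:`UndefinedValidityError` is raised.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    mask = labels != -1
    if np.unique(labels[mask]).size < 2:
        raise UndefinedValidityError("validity needs at least 2 non-noise clusters")
    Xv, lv = X[mask], labels[mask]
    return ClusterValidity(
        mean_silhouette=float(silhouette_score(Xv, lv)),
        silhouettes=silhouette_samples(Xv, lv),
        davies_bouldin=float(davies_bouldin_score(Xv, lv)),
    )


def assignments_table(table: pd.DataFrame, labels) -> pd.DataFrame:
    out = table.copy()
    out["cluster"] = np.asarray(labels)
    return out


def cluster_statistics(
    table: pd.DataFrame, labels, columns=("estrada", "wiener", "gutman")
) -> pd.DataFrame:
    """Per-cluster descriptive statistics with 95% and 99% normal-theory
    confidence intervals on the mean."""
    from scipy import stats

    out_rows = []
    df = assignments_table(table, labels)
    for cluster, grp in df.groupby("cluster"):
        for col in columns:
            vals = grp[col].to_numpy(dtype=float)
            m, s, n = vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0, len(vals)
            row = {"cluster": cluster, "variable": col, "n": n, "mean": m, "std": s}
            for level in (0.95, 0.99):
                if n > 1 and s > 0:
                    half = stats.t.ppf(0.5 + level / 2, n - 1) * s / np.sqrt(n)
                else:
                    half = 0.0
                row[f"ci{int(level * 100)}_low"] = m - half
                row[f"ci{int(level * 100)}_high"] = m + half
            out_rows.append(row)
    return pd.DataFrame(out_rows)
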