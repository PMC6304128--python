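"""Habitat similarity among natal, available and established territories.

The pooled feature table (territory variables + year) is standardized,
reduced to five principal components, and clustered; two territories are
"similar" when they land in the same cluster.  The NHBD indicator of a
record is 1 iff its cluster equals the cluster of the focal disperser's
natal territory.  A continuous alternative — Euclidean distance to the
natal territory in PC space — is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances
from sklearn.utils import check_random_state
from sklearn.utils.validation import validate_data

META_COLUMNS = ("disperser_id", "role", "point_index")
CLUSTER_METHODS = ("kmeans", "pam", "hierarchical")
N_COMPONENTS_DEFAULT = 5
K_DEFAULT = 6
K_SWEEP = tuple(range(4, 11))


def build_feature_matrix(
    records: pd.DataFrame,
    variables: Sequence[str] | None = None,
    meta_columns: Sequence[str] = META_COLUMNS,
) -> pd.DataFrame:
    """Standardized pooled feature matrix with year appended.

    ``records`` holds one row per territory record (natal, available or
    established) with the meta columns, a ``year`` column, and the
    habitat variables.  Standardization (mean 0, sd 1) is computed once
    over the pooled rows.  Zero-variance columns are rejected by name.
    """
    missing = set(meta_columns) - set(records.columns)
    if missing:
        raise ValueError(f"records missing meta columns: {sorted(missing)}")
    if variables is None:
        variables = [
            c for c in records.columns if c not in meta_columns and c != "year"
        ]
    cols = list(variables) + ["year"]
    X = records[cols].astype(float)
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    sd = X.std(ddof=0)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance columns: {dead}")
    Z = (X - X.mean()) / sd
    Z.index = pd.MultiIndex.from_frame(records[list(meta_columns)])
    return Z


def pca_scores(matrix, n_components: int = N_COMPONENTS_DEFAULT) -> np.ndarray:
    """Scores on the leading principal components of the column covariance.

    Components are ordered by decreasing explained variance.  Sign is
    fixed by convention: within each component the loading of largest
    magnitude is made positive.
    """
    X = np.asarray(matrix, float)
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds the number of columns")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.sign(
        pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)]
    )
    return scores * flip


class KMedoids(ClusterMixin, BaseEstimator):
    """Seeded k-medoids by alternating (Voronoi) iteration.

    Points are assigned to the nearest medoid; each medoid is then moved
    to the cluster member minimizing the within-cluster distance sum,
    until assignments stabilize.  Multiple restarts keep the partition of
    lowest total cost.  Operates on a precomputed pairwise Euclidean
    distance matrix, so it suits the few-thousand-row territory tables
    this package produces.
    """

    def __init__(self, n_clusters: int = 8, n_init: int = 5, max_iter: int = 100,
                 random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=self.n_clusters)
        rng = check_random_state(self.random_state)
        D = pairwise_distances(X)
        n = len(X)
        best_cost, best_medoids, best_labels = np.inf, None, None
        for _ in range(self.n_init):
            medoids = rng.choice(n, self.n_clusters, replace=False)
            for _ in range(self.max_iter):
                labels = D[:, medoids].argmin(axis=1)
                new_medoids = medoids.copy()
                for k in range(self.n_clusters):
                    members = np.flatnonzero(labels == k)
                    if len(members) == 0:
                        # revive an empty cluster on the worst-served point
                        worst = D[np.arange(n), medoids[labels]].argmax()
                        new_medoids[k] = worst
                        continue
                    within = D[np.ix_(members, members)].sum(axis=1)
                    new_medoids[k] = members[within.argmin()]
                if np.array_equal(new_medoids, medoids):
                    break
                medoids = new_medoids
            labels = D[:, medoids].argmin(axis=1)
            cost = D[np.arange(n), medoids[labels]].sum()
            if cost < best_cost:
                best_cost, best_medoids, best_labels = cost, medoids, labels
        self.medoid_indices_ = best_medoids
        self.cluster_centers_ = X[best_medoids]
        self.labels_ = best_labels
        self.inertia_ = best_cost
        return self

    def predict(self, X):
        X = validate_data(self, X, reset=False)
        return pairwise_distances(X, self.cluster_centers_).argmin(axis=1)


@dataclass(frozen=True)
class ClusterModel:
    """A fitted habitat-type partition of the territory records."""

    method: str
    k: int
    labels: np.ndarray  # cluster ids 1..k, one per row of the score matrix
    estimator: object | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, int)
        if lab.min() < 1 or lab.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if len(np.unique(lab)) != self.k:
            raise ValueError("all k clusters must be non-empty")
        object.__setattr__(self, "labels", lab)


def cluster_territories(
    scores: np.ndarray, method: str = "kmeans", k: int = K_DEFAULT, seed=None
) -> ClusterModel:
    """Partition territory PC scores into ``k`` habitat types.

    ``kmeans`` runs 25 seeded restarts keeping the lowest within-cluster
    sum of squares; ``pam`` is the seeded k-medoids above; ``hierarchical``
    cuts a Ward dendrogram at ``k`` groups.
    """
    scores = np.asarray(scores, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if method not in CLUSTER_METHODS:
        raise ValueError(f"method must be one of {CLUSTER_METHODS}")
    n_distinct = len(np.unique(scores, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    rs = None if seed is None else int(np.random.default_rng(seed).integers(2**31 - 1))
    if method == "kmeans":
        est = KMeans(n_clusters=k, n_init=25, random_state=rs).fit(scores)
    elif method == "pam":
        est = KMedoids(n_clusters=k, n_init=5, random_state=rs).fit(scores)
    else:
        est = AgglomerativeClustering(n_clusters=k, linkage="ward").fit(scores)
    return ClusterModel(method, k, est.labels_ + 1, est)


def nhbd_covariates(
    model: ClusterModel, matrix: pd.DataFrame, scores: np.ndarray
) -> pd.DataFrame:
    """NHBD indicator and continuous natal distance per territory record.

    ``matrix`` is the standardized feature matrix (rows aligned with
    ``scores`` and ``model.labels``) carrying the (disperser_id, role,
    point_index) MultiIndex.  The indicator of a record is 1 iff its
    cluster equals its disperser's natal-territory cluster; the distance
    is Euclidean in PC-score space (larger = less similar).
    """
    scores = np.asarray(scores, float)
    if not (len(matrix) == len(scores) == len(model.labels)):
        raise ValueError("matrix, scores and cluster labels must align by row")
    ids = matrix.index.get_level_values("disperser_id")
    roles = matrix.index.get_level_values("role")
    natal_pos: dict = {}
    for i, (d, r) in enumerate(zip(ids, roles)):
        if r == "natal":
            natal_pos[d] = i
    missing = sorted(set(ids) - set(natal_pos))
    if missing:
        raise ValueError(f"dispersers missing a natal record: {missing[:5]}")
    npos = np.asarray([natal_pos[d] for d in ids])
    indicator = (model.labels == model.labels[npos]).astype(int)
    dist = np.linalg.norm(scores - scores[npos], axis=1)
    return pd.DataFrame(
        {"nhbd_indicator": indicator, "natal_distance": dist}, index=matrix.index
    )
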