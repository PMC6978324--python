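"""Microstate discretization and structural clustering.

k-means (k-means++ seeding, Lloyd refinement with a farthest-point rescue
for emptied clusters) discretizes the TICA space into microstates;
average-linkage (UPGMA) agglomeration on pairwise RMSD drives seeding-style
frame selection and representative (medoid) extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import kmeans_plusplus

from .structures_features import FeatureMatrix, TrajectoryEnsemble, kabsch_rmsd
from .synthetic_dynamics import DiscreteTrajectory

__all__ = [
    "KMeansModel",
    "LinkageResult",
    "kmeans_fit",
    "assign",
    "average_linkage",
    "select_medoids",
]


@dataclass
class KMeansModel:
    centers: np.ndarray
    seed: int
    inertia: float
    n_iter: int


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, float)


def _nearest(X: np.ndarray, centers: np.ndarray, chunk: int = 65536):
    """Nearest-centre labels and squared distances; argmin breaks ties low."""
    labels = np.empty(len(X), dtype=np.int64)
    dist2 = np.empty(len(X))
    for s in range(0, len(X), chunk):
        d = cdist(X[s : s + chunk], centers, "sqeuclidean")
        labels[s : s + chunk] = np.argmin(d, axis=1)
        dist2[s : s + chunk] = d[np.arange(len(d)), labels[s : s + chunk]]
    return labels, dist2


def kmeans_fit(
    X, k: int, seed: int = 1234, max_iter: int = 100, tol: float = 1e-6
) -> KMeansModel:
    """Lloyd k-means with k-means++ initialization, deterministic in ``seed``.

    Emptied clusters are re-seeded from the point farthest from its centre.
    The within-cluster inertia is verified non-increasing every iteration.
    """
    arr = _as_array(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(arr):
        raise ValueError(f"k={k} exceeds the number of points ({len(arr)})")
    centers, _ = kmeans_plusplus(arr, n_clusters=k, random_state=seed)
    prev_inertia = np.inf
    for it in range(max_iter):
        labels, dist2 = _nearest(arr, centers)
        inertia = float(dist2.sum())
        assert inertia <= prev_inertia + 1e-9 * max(1.0, prev_inertia), (
            "Lloyd iteration increased inertia"
        )
        new_centers = centers.copy()
        for c in range(k):
            mask = labels == c
            if mask.any():
                new_centers[c] = arr[mask].mean(axis=0)
            else:
                new_centers[c] = arr[np.argmax(dist2)]
                dist2[np.argmax(dist2)] = 0.0
        shift = float(np.sqrt(np.sum((new_centers - centers) ** 2, axis=1)).max())
        centers = new_centers
        prev_inertia = inertia
        if shift < tol:
            break
    _, dist2 = _nearest(arr, centers)
    return KMeansModel(centers=centers, seed=seed, inertia=float(dist2.sum()), n_iter=it + 1)


def assign(model: KMeansModel, X, lag_unit: float = 1.0) -> DiscreteTrajectory:
    """Map frames to nearest centres (Euclidean; ties to the lowest index)."""
    arr = _as_array(X)
    if arr.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {arr.shape[1]} columns, "
            f"centers have {model.centers.shape[1]}"
        )
    labels, _ = _nearest(arr, model.centers)
    return DiscreteTrajectory(labels, lag_unit=lag_unit)


@dataclass
class LinkageResult:
    merges: np.ndarray  # (n-1, 2) merged cluster ids, scipy convention
    heights: np.ndarray  # (n-1,) non-decreasing merge heights
    labels: np.ndarray  # flat labels in [0, n_clusters)
    n_clusters: int
    representatives: np.ndarray  # medoid index per cluster, by label


def average_linkage(distance_matrix: np.ndarray, n_clusters: int) -> LinkageResult:
    """UPGMA agglomeration of a square distance matrix.

    The flat partition cuts the merge tree after the first ``n - n_clusters``
    merges, guaranteeing exactly ``n_clusters`` clusters.  Each cluster's
    representative is its medoid (minimum mean distance to co-members).
    """
    D = np.asarray(distance_matrix, float)
    n = len(D)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12) or np.any(D < -1e-12):
        raise ValueError("distance matrix must be non-negative with zero diagonal")
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters must be in [1, n]")

    Z = linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]

    # union-find over the first n - n_clusters merges
    parent = np.arange(n + len(Z))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for m in range(n - n_clusters):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        node = n + m
        parent[find(a)] = node
        parent[find(b)] = node
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)

    reps = np.empty(n_clusters, dtype=np.int64)
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        sub = D[np.ix_(members, members)]
        reps[c] = members[np.argmin(sub.mean(axis=1))]
    return LinkageResult(Z[:, :2].astype(int), heights, labels, n_clusters, reps)


def select_medoids(
    ensemble: TrajectoryEnsemble,
    labels: np.ndarray,
    selection: np.ndarray,
) -> list[dict]:
    """Per-cluster medoid frames under pairwise Kabsch RMSD on ``selection``.

    Returns one record per cluster — ``{"label", "population", "frame"}`` —
    sorted by descending population.
    """
    labels = np.asarray(labels)
    if len(labels) != len(ensemble):
        raise ValueError("labels must cover all frames")
    out = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) == 1:
            medoid = int(members[0])
        else:
            sub = np.zeros((len(members), len(members)))
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    _, _, r = kabsch_rmsd(
                        ensemble.frames[members[i]],
                        ensemble.frames[members[j]],
                        fit_selection=selection,
                    )
                    sub[i, j] = sub[j, i] = r
            medoid = int(members[np.argmin(sub.mean(axis=1))])
        out.append({"label": int(lab), "population": int(len(members)), "frame": medoid})
    out.sort(key=lambda r: (-r["population"], r["label"]))
    return out
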