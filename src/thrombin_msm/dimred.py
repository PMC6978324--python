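"""Principal component and time-lagged independent component analysis.

PCA diagonalizes the covariance of a (structure-survey style) feature
matrix.  TICA solves the symmetrized generalized eigenproblem
C(tau) v = lambda C(0) v over per-trajectory lagged pairs, yielding the
linear combinations with the slowest decorrelation — the coordinates in
which metastable exchange is resolved.  The reversible (symmetrized)
estimator is used: with a common mean for the leading and lagged halves,
C(0) +/- C(tau) are positive semidefinite, so |lambda| <= 1 up to the
regularization shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .structures_features import FeatureMatrix

__all__ = ["PCAModel", "TICAModel", "fit_pca", "fit_tica", "project"]


@dataclass
class PCAModel:
    mean: np.ndarray
    eigenvalues: np.ndarray  # descending, >= 0
    eigenvectors: np.ndarray  # orthonormal columns
    n_components: int

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


@dataclass
class TICAModel:
    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray  # symmetrized
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, C0-orthonormal
    regularization: float
    n_components: int


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, float)


def fit_pca(X, n_components: int | None = None) -> PCAModel:
    """Eigendecomposition of the covariance of centred ``X``."""
    arr = _as_array(X)
    if arr.ndim != 2 or len(arr) < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    mean = arr.mean(axis=0)
    centred = arr - mean
    cov = centred.T @ centred / (len(arr) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    k = arr.shape[1] if n_components is None else min(n_components, arr.shape[1])
    return PCAModel(mean, vals, vecs, n_components=k)


def fit_tica(
    trajectories: Sequence, lag: int, regularization: float = 1e-6, n_components: int = 4
) -> TICAModel:
    """Reversible TICA over per-trajectory lagged pairs.

    Trajectories shorter than ``lag`` + 1 frames contribute no pairs and are
    excluded with a warning; C(0) is shrunk by
    ``regularization * mean(diag C0) * I`` to keep the generalized problem
    well posed for near-constant columns (e.g. the binary sodium flag).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    arrays = []
    for i, X in enumerate(trajectories):
        arr = _as_array(X)
        if len(arr) <= lag:
            warnings.warn(f"trajectory {i} shorter than lag {lag}; excluded", stacklevel=2)
            continue
        arrays.append(arr)
    if not arrays:
        raise ValueError("no trajectory longer than the lag")
    d = arrays[0].shape[1]

    n_pairs = 0
    s = np.zeros(d)
    for arr in arrays:
        a, btail = arr[:-lag], arr[lag:]
        n_pairs += len(a)
        s += a.sum(axis=0) + btail.sum(axis=0)
    mean = s / (2 * n_pairs)

    c0 = np.zeros((d, d))
    ct = np.zeros((d, d))
    for arr in arrays:
        a = arr[:-lag] - mean
        btail = arr[lag:] - mean
        c0 += a.T @ a + btail.T @ btail
        ct += a.T @ btail
    c0 /= 2 * n_pairs
    ct = (ct + ct.T) / (2 * n_pairs)

    shift = regularization * (np.trace(c0) / d)
    c0_reg = c0 + shift * np.eye(d)
    vals, vecs = eigh(ct, c0_reg)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.any(np.abs(vals) > 1.0 + 1e-6):
        raise RuntimeError("TICA eigenvalues exceed 1: estimator inconsistency")
    return TICAModel(
        lag=lag, mean=mean, c0=c0, ctau=ct,
        eigenvalues=vals, eigenvectors=vecs,
        regularization=regularization, n_components=min(n_components, d),
    )


def project(model: PCAModel | TICAModel, X) -> FeatureMatrix:
    """Project ``X`` onto the model's retained components."""
    arr = _as_array(X)
    if arr.shape[1] != len(model.mean):
        raise ValueError(
            f"dimension mismatch: data has {arr.shape[1]} columns, model expects {len(model.mean)}"
        )
    k = model.n_components
    if k < 1:
        raise ValueError("no components retained")
    prefix = "PC" if isinstance(model, PCAModel) else "TIC"
    Y = (arr - model.mean) @ model.eigenvectors[:, :k]
    cols = {f"{prefix}{i + 1}": Y[:, i] for i in range(k)}
    units = {c: "arbitrary" for c in cols}
    return FeatureMatrix(pd.DataFrame(cols), units)
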