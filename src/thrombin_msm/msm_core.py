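"""Markov state model estimation, validation and coarse-graining.

Sliding-window transition counts, ergodic trimming to the largest strongly
connected set, reversible maximum-likelihood estimation (detailed-balance
constrained, via the standard self-consistent fixed-point iteration),
spectral analysis and implied timescales, Chapman--Kolmogorov testing,
PCCA+ metastable lumping, stationary probabilities, mean first passage
times, and trajectory-bootstrap uncertainty quantification.

All transition matrices are row-stochastic; reversibility means
pi_i T_ij = pi_j T_ji for the stationary distribution pi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .synthetic_dynamics import DiscreteTrajectory

__all__ = [
    "CountMatrix",
    "MSMModel",
    "PCCAResult",
    "UncertaintyEnsemble",
    "count_transitions",
    "largest_connected_set",
    "estimate_reversible",
    "estimate_msm",
    "implied_timescales",
    "ck_test",
    "pcca_plus",
    "mfpt",
    "bootstrap_ensemble",
]


def _states_of(d) -> np.ndarray:
    return d.states if isinstance(d, DiscreteTrajectory) else np.asarray(d, dtype=np.int64)


def _lag_unit_of(dtrajs) -> float:
    units = {d.lag_unit for d in dtrajs if isinstance(d, DiscreteTrajectory)}
    if len(units) > 1:
        raise ValueError("trajectories disagree on the physical time per step")
    return units.pop() if units else 1.0


@dataclass
class CountMatrix:
    counts: np.ndarray  # (n, n) integer
    lag: int  # frames
    total: int
    state_map: np.ndarray  # row/col -> original microstate index
    lag_unit: float = 1.0  # physical time per frame

    @property
    def n_states(self) -> int:
        return len(self.counts)


@dataclass
class MSMModel:
    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    eigenvalues: np.ndarray  # descending by modulus, lambda_1 = 1
    right_eigenvectors: np.ndarray
    left_eigenvectors: np.ndarray
    lag: int  # frames
    lag_time: float  # physical units
    active_set: np.ndarray  # microstate indices (original labels)

    @property
    def n_states(self) -> int:
        return len(self.transition_matrix)

    def timescales(self, k: int | None = None) -> np.ndarray:
        """Implied timescales -lag_time/ln|lambda_i|, i >= 2 (NaN if undefined)."""
        lams = self.eigenvalues[1:k if k is None else k + 1]
        out = np.full(len(lams), np.nan)
        ok = (lams > 0) & (lams < 1 - 1e-12)
        out[ok] = -self.lag_time / np.log(lams[ok])
        return out


@dataclass
class PCCAResult:
    memberships: np.ndarray  # (n_micro, n_meta), rows sum to 1
    crisp: np.ndarray  # argmax membership per microstate
    coarse_stationary: np.ndarray  # (n_meta,), sums to 1
    n_meta: int

    def metastable_sets(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.crisp == a) for a in range(self.n_meta)]


@dataclass
class UncertaintyEnsemble:
    coarse_samples: np.ndarray  # (n_kept, n_meta)
    mfpt_samples: np.ndarray  # (n_kept, n_meta, n_meta)
    coarse_interval: np.ndarray  # (2, n_meta): 2.5 / 97.5 percentiles
    mfpt_interval: np.ndarray  # (2, n_meta, n_meta)
    point_coarse: np.ndarray
    point_mfpt: np.ndarray
    n_skipped: int


def count_transitions(dtrajs: Sequence, lag: int, mode: str = "sliding") -> CountMatrix:
    """Sliding-window transition counts at ``lag`` frames, per trajectory."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode != "sliding":
        raise ValueError("only sliding counting is implemented")
    dtrajs = list(dtrajs)
    arrays = [_states_of(d) for d in dtrajs]
    n = int(max(a.max() for a in arrays)) + 1
    C = np.zeros((n, n), dtype=np.int64)
    total = 0
    for a in arrays:
        if len(a) <= lag:
            continue
        np.add.at(C, (a[:-lag], a[lag:]), 1)
        total += len(a) - lag
    if total == 0:
        raise ValueError(f"no trajectory longer than lag {lag}")
    return CountMatrix(C, lag, total, np.arange(n), _lag_unit_of(dtrajs))


def largest_connected_set(C: CountMatrix | np.ndarray) -> np.ndarray:
    """Vertices of the largest strongly connected component of C_ij > 0."""
    counts = C.counts if isinstance(C, CountMatrix) else np.asarray(C)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    n_comp, labels = connected_components(csr_matrix(counts > 0), connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    return np.flatnonzero(labels == np.argmax(sizes))


def _restrict(C: CountMatrix, active: np.ndarray) -> CountMatrix:
    sub = C.counts[np.ix_(active, active)]
    return CountMatrix(sub, C.lag, C.total, C.state_map[active], C.lag_unit)


def _spectrum(T: np.ndarray, pi: np.ndarray):
    sq = np.sqrt(pi)
    S = (sq[:, None] * T) / sq[None, :]
    S = 0.5 * (S + S.T)
    vals, U = np.linalg.eigh(S)
    order = np.argsort(-np.abs(vals))
    vals, U = vals[order], U[:, order]
    right = U / sq[:, None]
    left = U * sq[:, None]
    # normalize the stationary pair: right_1 = 1, left_1 = pi
    s = right[0, 0]
    right[:, 0] /= s
    left[:, 0] *= s
    return vals, right, left


def estimate_reversible(
    C: CountMatrix, tol: float = 1e-10, max_sweeps: int = 1_000_000
) -> MSMModel:
    """Reversible maximum-likelihood transition matrix from connected counts.

    Self-consistent fixed-point iteration on the unnormalized flux matrix x:
        x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)
    converging to the detailed-balance constrained MLE; T_ij = x_ij / x_i
    and pi = x_i / sum(x).
    """
    counts = np.asarray(C.counts, float)
    n = len(counts)
    c_row = counts.sum(axis=1)
    if np.any(c_row == 0):
        raise ValueError("count matrix has empty rows; trim to the connected set first")
    sym = counts + counts.T
    mask = sym > 0
    x = sym / sym.sum()
    for _ in range(max_sweeps):
        xi = x.sum(axis=1)
        q = c_row / xi
        denom = q[:, None] + q[None, :]
        x_new = np.where(mask, sym / denom, 0.0)
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x)) / max(x.max(), 1e-300)
        x = x_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"reversible MLE did not converge: residual {delta:.3e}")
    xi = x.sum(axis=1)
    T = x / xi[:, None]
    pi = xi / xi.sum()
    vals, right, left = _spectrum(T, pi)
    return MSMModel(
        transition_matrix=T,
        stationary_distribution=pi,
        eigenvalues=vals,
        right_eigenvectors=right,
        left_eigenvectors=left,
        lag=C.lag,
        lag_time=C.lag * C.lag_unit,
        active_set=C.state_map.copy(),
    )


def estimate_msm(dtrajs: Sequence, lag: int) -> MSMModel:
    """Counts -> largest connected set -> reversible MLE, in one call."""
    C = count_transitions(dtrajs, lag)
    active = largest_connected_set(C)
    return estimate_reversible(_restrict(C, active))


def implied_timescales(
    dtrajs: Sequence, lags: Sequence[int], n_timescales: int = 5
) -> pd.DataFrame:
    """Implied timescale table t_i(tau) = -tau/ln lambda_i(tau), physical units.

    Non-positive (or unit) eigenvalues yield NaN entries — flagged, not fatal.
    """
    rows = []
    for lag in lags:
        model = estimate_msm(dtrajs, lag)
        ts = model.timescales(n_timescales)
        rows.append(
            {"lag": lag, "lag_time": model.lag_time}
            | {f"t{i + 2}": ts[i] if i < len(ts) else np.nan for i in range(n_timescales)}
        )
    return pd.DataFrame(rows)


def pcca_plus(T: np.ndarray | MSMModel, n_meta: int = 2) -> PCCAResult:
    """PCCA+ soft lumping of microstates into ``n_meta`` metastable states.

    Memberships come from the inner-simplex vertex construction on the
    dominant right eigenvectors; for n_meta = 2 this reduces to a monotone
    affine transform of the second right eigenvector.  Coarse stationary
    probabilities are pi-weighted membership sums.
    """
    if isinstance(T, MSMModel):
        model = T
    else:
        T = np.asarray(T, float)
        pi = _stationary(T)
        vals, right, left = _spectrum(T, pi)
        model = MSMModel(T, pi, vals, right, left, 1, 1.0, np.arange(len(T)))
    n = model.n_states
    if not 1 <= n_meta <= n:
        raise ValueError("n_meta out of range")
    # metastability lives in the largest *real* eigenvalues (the stored
    # spectrum is modulus-ordered, which can rank fast oscillatory modes high)
    order = np.argsort(-model.eigenvalues)
    lams = model.eigenvalues[order]
    if n_meta < n:
        gap = float(lams[n_meta - 1] - lams[n_meta])
        if gap <= 1e-12:
            raise ValueError(
                f"no spectral gap after eigenvalue {n_meta} "
                f"(lambda_{n_meta}={lams[n_meta - 1]:.6f}, "
                f"lambda_{n_meta + 1}={lams[n_meta]:.6f}, gap={gap:.2e})"
            )
    X = model.right_eigenvectors[:, order[:n_meta]].copy()
    X[:, 0] = 1.0

    # inner-simplex index search: vertices of the eigenvector simplex
    idx = np.zeros(n_meta, dtype=np.int64)
    Xc = X.copy()
    idx[0] = np.argmax(np.sum(Xc**2, axis=1))
    Xc = Xc - Xc[idx[0]]
    for j in range(1, n_meta):
        norms = np.sum(Xc**2, axis=1)
        idx[j] = np.argmax(norms)
        v = Xc[idx[j]]
        nv = float(v @ v)
        if nv > 0:
            Xc = Xc - np.outer(Xc @ v, v) / nv
    A = np.linalg.inv(X[idx])
    chi = X @ A
    chi = np.clip(chi, 0.0, 1.0)
    chi /= chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)
    coarse = chi.T @ model.stationary_distribution
    coarse = coarse / coarse.sum()
    return PCCAResult(chi, crisp, coarse, n_meta)


def _stationary(T: np.ndarray) -> np.ndarray:
    # sum over the full unit eigenspace: keeps every block of a reducible
    # chain weighted, so PCCA on exactly block-diagonal matrices stays sane
    vals, vecs = np.linalg.eig(T.T)
    unit = np.abs(vals - 1.0) < 1e-10
    if not unit.any():
        unit = np.abs(vals - 1.0) == np.abs(vals - 1.0).min()
    pi = np.abs(np.real(vecs[:, unit])).sum(axis=1)
    return pi / pi.sum()


def mfpt(model: MSMModel, source: Sequence[int], target: Sequence[int]) -> float:
    """Mean first passage time (physical units) from ``source`` to ``target``.

    Solves m_i = lag_time + sum_j T_ij m_j with m = 0 on the target, then
    averages m over the source with the stationary distribution restricted
    to the source and renormalized.
    """
    source = np.asarray(source, dtype=np.int64)
    target = np.asarray(target, dtype=np.int64)
    n = model.n_states
    if len(source) == 0 or len(target) == 0:
        raise ValueError("source and target must be non-empty")
    if np.intersect1d(source, target).size:
        raise ValueError("source and target must be disjoint")
    if source.max() >= n or target.max() >= n:
        raise ValueError("state index outside the active set")
    free = np.setdiff1d(np.arange(n), target)
    T = model.transition_matrix
    A = np.eye(len(free)) - T[np.ix_(free, free)]
    try:
        m_free = np.linalg.solve(A, np.full(len(free), model.lag_time))
    except np.linalg.LinAlgError as exc:
        raise ValueError("target set unreachable from the source") from exc
    m = np.zeros(n)
    m[free] = m_free
    w = model.stationary_distribution[source]
    return float(m[source] @ (w / w.sum()))


def _set_persistence(T: np.ndarray, pi: np.ndarray, members: np.ndarray, k: int) -> float:
    Tk = np.linalg.matrix_power(T, k)
    w = pi[members] / pi[members].sum()
    return float(w @ Tk[np.ix_(members, members)].sum(axis=1))


def ck_test(
    model: MSMModel,
    dtrajs: Sequence,
    sets: PCCAResult,
    K: int = 5,
    n_boot: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Chapman--Kolmogorov test on the metastable partition.

    Per set A and step k: ``predicted`` is the stationary-weighted
    probability of remaining in A after k model steps, T(tau)^k; ``estimated``
    is the same quantity from an MSM re-estimated at lag k*tau.  Estimated
    values carry trajectory-bootstrap standard errors.
    """
    arrays = [_states_of(d) for d in dtrajs]
    lag_unit = _lag_unit_of(list(dtrajs))
    max_len = max(len(a) for a in arrays)
    rows = []
    rng = np.random.default_rng(seed)
    meta_sets = sets.metastable_sets()
    for k in range(1, K + 1):
        klag = k * model.lag
        if klag >= max_len:
            warnings.warn(f"insufficient data at lag {klag}; CK truncated at k={k - 1}",
                          stacklevel=2)
            break
        try:
            mk = estimate_msm([DiscreteTrajectory(a, lag_unit) for a in arrays], klag)
        except ValueError:
            warnings.warn(f"no connected model at lag {klag}; CK truncated", stacklevel=2)
            break
        boot_vals: list[list[float]] = [[] for _ in meta_sets]
        for _ in range(n_boot):
            pick = rng.integers(0, len(arrays), size=len(arrays))
            try:
                mb = estimate_msm(
                    [DiscreteTrajectory(arrays[i], lag_unit) for i in pick], klag
                )
            except ValueError:
                continue
            for a, members in enumerate(meta_sets):
                mem_b = np.intersect1d(mb.active_set, model.active_set[members])
                loc = np.searchsorted(mb.active_set, mem_b)
                if len(loc):
                    boot_vals[a].append(
                        _set_persistence(mb.transition_matrix, mb.stationary_distribution, loc, 1)
                    )
        for a, members in enumerate(meta_sets):
            pred = _set_persistence(
                model.transition_matrix, model.stationary_distribution, members, k
            )
            mem_k = np.intersect1d(mk.active_set, model.active_set[members])
            loc = np.searchsorted(mk.active_set, mem_k)
            est = _set_persistence(mk.transition_matrix, mk.stationary_distribution, loc, 1)
            std = float(np.std(boot_vals[a])) if boot_vals[a] else np.nan
            rows.append({"set": a, "k": k, "predicted": pred, "estimated": est,
                         "estimated_std": std})
    return pd.DataFrame(rows)


def bootstrap_ensemble(
    dtrajs: Sequence,
    lag: int,
    n_meta: int = 2,
    n_resamples: int = 100,
    seed: int = 0,
) -> UncertaintyEnsemble:
    """Trajectory bootstrap of coarse stationary probabilities and MFPTs.

    Trajectories are resampled with replacement; each resample is re-run
    through estimation, PCCA+ lumping and MFPT evaluation.  Metastable
    identities are matched to the full-data point estimate by maximal
    microstate-membership overlap.  Resamples losing connectivity (or the
    spectral gap) are skipped; more than 50% skipped is an error.
    """
    dtrajs = list(dtrajs)
    if len(dtrajs) < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    arrays = [_states_of(d) for d in dtrajs]
    lag_unit = _lag_unit_of(dtrajs)

    def run(traj_arrays):
        model = estimate_msm([DiscreteTrajectory(a, lag_unit) for a in traj_arrays], lag)
        pcca = pcca_plus(model, n_meta)
        sets = pcca.metastable_sets()
        M = np.zeros((n_meta, n_meta))
        for a in range(n_meta):
            for b in range(n_meta):
                if a != b:
                    M[a, b] = mfpt(model, sets[a], sets[b])
        return model, pcca, M

    point_model, point_pcca, point_mfpt = run(arrays)
    rng = np.random.default_rng(seed)
    coarse_samples, mfpt_samples = [], []
    n_skipped = 0
    for _ in range(n_resamples):
        pick = rng.integers(0, len(arrays), size=len(arrays))
        try:
            model, pcca, M = run([arrays[i] for i in pick])
        except (ValueError, RuntimeError):
            n_skipped += 1
            continue
        # match metastable identities to the point estimate via overlap
        overlap = np.zeros((n_meta, n_meta))
        ref_crisp_global = {}
        for a in range(n_meta):
            ref_crisp_global[a] = set(point_model.active_set[point_pcca.crisp == a])
        for a in range(n_meta):
            states_a = set(model.active_set[pcca.crisp == a])
            for b in range(n_meta):
                overlap[a, b] = len(states_a & ref_crisp_global[b])
        perm = np.argmax(overlap, axis=1)
        if len(set(perm)) < n_meta:  # ambiguous match
            n_skipped += 1
            continue
        coarse = np.empty(n_meta)
        Mp = np.empty((n_meta, n_meta))
        for a in range(n_meta):
            coarse[perm[a]] = pcca.coarse_stationary[a]
            for b in range(n_meta):
                Mp[perm[a], perm[b]] = M[a, b]
        coarse_samples.append(coarse)
        mfpt_samples.append(Mp)
    if n_skipped > n_resamples / 2:
        raise RuntimeError(
            f"{n_skipped}/{n_resamples} bootstrap resamples lost connectivity"
        )
    cs = np.asarray(coarse_samples)
    ms = np.asarray(mfpt_samples)
    return UncertaintyEnsemble(
        coarse_samples=cs,
        mfpt_samples=ms,
        coarse_interval=np.percentile(cs, [2.5, 97.5], axis=0),
        mfpt_interval=np.percentile(ms, [2.5, 97.5], axis=0),
        point_coarse=point_pcca.coarse_stationary,
        point_mfpt=point_mfpt,
        n_skipped=n_skipped,
    )
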