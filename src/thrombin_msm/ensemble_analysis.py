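"""Result-level analysis of MSM-weighted conformational ensembles.

Turns an estimated MSM plus its metastable lumping into the quantities a
population-shift study reports: equilibrium frame weights (microstate
stationary probability spread evenly over the frames observed in that
microstate, with uncertain microstates excluded by a membership cutoff),
per-state weighted feature distributions whose areas sum to one, free-energy
surfaces in the reduced space, RMSD-to-reference summaries, and circular
(von Mises kernel) dihedral entropies as a per-residue flexibility measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import i0, i1

from .msm_core import MSMModel, PCCAResult
from .structures_features import TrajectoryEnsemble, kabsch_rmsd
from .synthetic_dynamics import DiscreteTrajectory

__all__ = [
    "FrameWeights",
    "WeightedHistogram",
    "EntropyProfile",
    "frame_weights",
    "weighted_distribution",
    "free_energy_surface",
    "rmsd_to_reference_distribution",
    "dihedral_entropy",
    "entropy_profile",
]

EXCLUDED = -1


@dataclass
class FrameWeights:
    weights: np.ndarray  # per frame; 0 for excluded frames
    labels: np.ndarray  # metastable index per frame, EXCLUDED (-1) if dropped
    state_names: tuple[str, ...]
    cutoff: float

    def __post_init__(self) -> None:
        kept = self.labels != EXCLUDED
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if kept.any() and abs(self.weights[kept].sum() - 1.0) > 1e-8:
            raise ValueError("retained weights must sum to 1")

    def state_probability(self, a: int) -> float:
        return float(self.weights[self.labels == a].sum())


@dataclass
class WeightedHistogram:
    bin_edges: np.ndarray
    densities: dict[str, np.ndarray]  # state name -> density
    integrated: dict[str, float]  # state name -> total probability
    feature: str
    units: str


def frame_weights(
    dtrajs: Sequence,
    msm: MSMModel,
    pcca: PCCAResult,
    cutoff: float = 0.90,
    state_names: tuple[str, ...] = ("E", "Estar"),
) -> FrameWeights:
    """Per-frame equilibrium weights pi_i / N_i with a membership cutoff.

    Frames in microstate i receive weight pi_i / N_i (N_i = retained frames
    observed in i), so weighted averages reproduce stationary expectations
    exactly.  Microstates whose largest metastable membership does not
    exceed ``cutoff`` are excluded (uncertain affiliation), as are frames
    outside the active set; the remaining weights are renormalized.
    """
    concat = np.concatenate(
        [d.states if isinstance(d, DiscreteTrajectory) else np.asarray(d) for d in dtrajs]
    )
    n_micro_orig = int(concat.max()) + 1
    to_active = np.full(max(n_micro_orig, msm.active_set.max() + 1), -1, dtype=np.int64)
    to_active[msm.active_set] = np.arange(msm.n_states)
    active_of_frame = to_active[concat]

    confident = pcca.memberships.max(axis=1) > cutoff
    labels = np.full(len(concat), EXCLUDED, dtype=np.int64)
    weights = np.zeros(len(concat))
    inside = active_of_frame >= 0
    keep = inside & confident[np.clip(active_of_frame, 0, None)]
    if not keep.any():
        raise ValueError(f"membership cutoff {cutoff} excludes every frame")
    kept_states = active_of_frame[keep]
    counts = np.bincount(kept_states, minlength=msm.n_states)
    pi = msm.stationary_distribution
    w_state = np.zeros(msm.n_states)
    observed = counts > 0
    w_state[observed] = pi[observed] / counts[observed]
    weights[keep] = w_state[kept_states]
    weights /= weights.sum()
    labels[keep] = pcca.crisp[kept_states]
    if len(state_names) < pcca.n_meta:
        raise ValueError("need one state name per metastable state")
    return FrameWeights(weights, labels, tuple(state_names), cutoff)


def _fd_edges(x: np.ndarray, n_min: int = 20) -> np.ndarray:
    q75, q25 = np.percentile(x, [75, 25])
    width = 2 * (q75 - q25) * len(x) ** (-1 / 3)
    lo, hi = float(x.min()), float(x.max())
    if width <= 0 or hi == lo:
        return np.linspace(lo - 0.5, hi + 0.5, n_min + 1)
    n = max(n_min, int(np.ceil((hi - lo) / width)))
    return np.linspace(lo, hi, n + 1)


def weighted_distribution(
    feature: np.ndarray,
    weights: FrameWeights,
    bins: int | np.ndarray | None = None,
    feature_name: str = "feature",
    units: str = "",
) -> WeightedHistogram:
    """Per-metastable-state weighted histograms on shared bins.

    The combined area under all state densities is 1; each state's
    integrated probability equals its coarse stationary probability over the
    retained microstates.  Bins default to Freedman--Diaconis on the pooled
    retained data.
    """
    feature = np.asarray(feature, float)
    if len(feature) != len(weights.weights):
        raise ValueError("feature and weights must be aligned")
    kept = weights.labels != EXCLUDED
    if bins is None:
        edges = _fd_edges(feature[kept])
    elif np.isscalar(bins):
        lo, hi = float(feature[kept].min()), float(feature[kept].max())
        if hi == lo:  # degenerate range: pad so bin widths stay positive
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, float)
    widths = np.diff(edges)
    densities, integrated = {}, {}
    n_states = int(weights.labels.max()) + 1
    for a in range(n_states):
        name = weights.state_names[a]
        mask = weights.labels == a
        if not mask.any():
            warnings.warn(f"metastable state {name} holds no frames", stacklevel=2)
            densities[name] = np.zeros(len(widths))
            integrated[name] = 0.0
            continue
        hist, _ = np.histogram(feature[mask], bins=edges, weights=weights.weights[mask])
        densities[name] = hist / widths
        integrated[name] = float(weights.weights[mask].sum())
    return WeightedHistogram(edges, densities, integrated, feature_name, units)


def free_energy_surface(
    reduced: np.ndarray,
    weights: np.ndarray | FrameWeights,
    kT: float = 1.0,
    grid: int = 80,
):
    """F(bin) = -kT ln(weighted density) on a 2-D grid, minimum shifted to 0.

    Returns (x_edges, y_edges, F) with unoccupied bins at +inf.
    """
    X = np.asarray(reduced, float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("free_energy_surface needs exactly 2 reduced columns")
    w = weights.weights if isinstance(weights, FrameWeights) else np.asarray(weights, float)
    H, xe, ye = np.histogram2d(X[:, 0], X[:, 1], bins=grid, weights=w)
    area = np.outer(np.diff(xe), np.diff(ye))
    dens = H / area
    with np.errstate(divide="ignore"):
        F = -kT * np.log(dens)
    F -= F[np.isfinite(F)].min()
    return xe, ye, F


def rmsd_to_reference_distribution(
    ensemble: TrajectoryEnsemble,
    reference_E: np.ndarray,
    reference_Estar: np.ndarray,
    selection: np.ndarray,
    weights: FrameWeights,
    bins: int | np.ndarray | None = None,
) -> dict:
    """Per-state RMSD summaries against the E and E* reference frames.

    Kabsch RMSD is fit and measured on ``selection`` (the loop heavy atoms in
    the published protocol).  Returns, per (state, reference) pair, the min,
    max and a weighted histogram.
    """
    refs = {"E_ref": np.asarray(reference_E, float), "Estar_ref": np.asarray(reference_Estar, float)}
    rmsds = {
        key: np.array(
            [kabsch_rmsd(f, ref, fit_selection=selection)[2] for f in ensemble.frames]
        )
        for key, ref in refs.items()
    }
    out: dict[str, dict] = {}
    for key, vals in rmsds.items():
        hist = weighted_distribution(vals, weights, bins, feature_name=f"RMSD_{key}",
                                     units="Angstrom")
        per_state = {}
        for a, name in enumerate(weights.state_names[: int(weights.labels.max()) + 1]):
            mask = weights.labels == a
            if mask.any():
                per_state[name] = {"min": float(vals[mask].min()),
                                   "max": float(vals[mask].max())}
        out[key] = {"summary": per_state, "histogram": hist, "values": vals}
    return out


def dihedral_entropy(
    angles: np.ndarray,
    bandwidth: float | None = None,
    kappa: float | None = None,
    weights: np.ndarray | None = None,
    grid_points: int = 360,
) -> float:
    """Differential entropy (nats) of a circular angle sample, in degrees.

    A von Mises kernel density with concentration ``kappa`` (from
    ``bandwidth`` via the reciprocal-squared rule kappa = 1/bandwidth^2;
    default kappa = 50) is evaluated on a uniform 360-point grid and the
    entropy -integral p ln p taken over the circle in radian measure.  The
    maximum-entropy (uniform) limit is ln(2 pi) ~ 1.8379 nats.
    """
    angles = np.radians(np.asarray(angles, float))
    if len(angles) < 10:
        raise ValueError("dihedral_entropy needs at least 10 angles")
    if kappa is None:
        kappa = 50.0 if bandwidth is None else 1.0 / bandwidth**2
    if weights is None:
        w = np.full(len(angles), 1.0 / len(angles))
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    grid = np.linspace(-np.pi, np.pi, grid_points, endpoint=False)
    # p(theta) = sum_i w_i exp(kappa cos(theta - theta_i)) / (2 pi I0(kappa))
    p = np.zeros(grid_points)
    for s in range(0, len(angles), 20_000):  # chunked: bounded memory at large n
        block = angles[s : s + 20_000]
        p += np.exp(kappa * np.cos(grid[:, None] - block[None, :])) @ w[s : s + 20_000]
    p /= 2 * np.pi * i0(kappa)
    dtheta = 2 * np.pi / grid_points
    p = p / (p.sum() * dtheta)  # guard against quadrature drift
    mask = p > 0
    return float(-np.sum(p[mask] * np.log(p[mask])) * dtheta)


def von_mises_entropy(kappa: float) -> float:
    """Closed-form differential entropy of the von Mises distribution."""
    return float(np.log(2 * np.pi * i0(kappa)) - kappa * i1(kappa) / i0(kappa))


@dataclass
class EntropyProfile:
    """Per-residue psi entropies for each (condition, state) combination."""

    table: pd.DataFrame  # columns: residue, condition, state, entropy_nats


def entropy_profile(
    angle_sets: dict[tuple[str, str, str], np.ndarray],
    weight_sets: dict[tuple[str, str, str], np.ndarray] | None = None,
    kappa: float = 50.0,
) -> EntropyProfile:
    """Entropy table from ``{(residue, condition, state): angles}`` samples."""
    rows = []
    for (residue, condition, state), angles in angle_sets.items():
        w = None if weight_sets is None else weight_sets.get((residue, condition, state))
        s = dihedral_entropy(angles, kappa=kappa, weights=w)
        if not -10.0 <= s <= np.log(2 * np.pi) + 1e-6:
            raise RuntimeError(f"entropy {s:.3f} outside the sanity range for {residue}")
        rows.append({"residue": residue, "condition": condition, "state": state,
                     "entropy_nats": s})
    return EntropyProfile(pd.DataFrame(rows))
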