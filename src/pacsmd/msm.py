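"""Markov-state-model post-analysis of sampled binding trajectories.

Microstates are defined by k-means on reaction-coordinate values, the lag
time is chosen where the implied timescales t_i(tau) = -tau / ln lambda_i(tau)
plateau, the transition matrix is estimated under detailed balance from
sliding-window transition counts (never across segment boundaries — cascade
segments are independent restarts), and the free-energy profile follows from
the stationary distribution, F_i = -k_B T ln(pi_i / max_k pi_k), so its
minimum is pinned to zero at the most populated microstate.

Caveat: trajectories produced by cascade selection are biased toward the
bound state; the resulting profile is the protocol's "rough" free-energy
landscape and is reported as-is, without reweighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .reaction_coordinates import RCSpec, evaluate_rc_pool

__all__ = [
    "DiscreteTrajectorySet",
    "TransitionModel",
    "cluster_microstates",
    "count_transitions",
    "largest_connected_set",
    "estimate_T",
    "implied_timescales",
    "select_lag",
    "stationary_distribution",
    "free_energy_profile",
    "profile_from_rc_segments",
    "profile_along_rc",
]

logger = logging.getLogger(__name__)


@dataclass
class DiscreteTrajectorySet:
    """Microstate index sequences, one per (cycle, replica) segment.

    Segments are never concatenated across distinct origins; transition
    counting respects segment boundaries.
    """

    segments: list[np.ndarray]
    n_states: int
    centers: np.ndarray
    origins: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.segments = [np.asarray(s, dtype=int).reshape(-1) for s in self.segments]
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim == 1:
            self.centers = self.centers[:, None]
        for s in self.segments:
            if s.size and (s.min() < 0 or s.max() >= self.n_states):
                raise ValueError("microstate index out of range")
        if self.origins is not None and len(self.origins) != len(self.segments):
            raise ValueError("origins/segments length mismatch")


@dataclass
class TransitionModel:
    """Estimated Markov model over the active (connected) microstates.

    ``active`` maps the model's state indices back to the clustering's
    microstate labels; ``centers`` are the active microstate centers.
    """

    lag: int
    counts: np.ndarray
    T: np.ndarray
    pi: np.ndarray
    timescales: np.ndarray
    free_energy: np.ndarray
    kBT: float
    centers: np.ndarray
    active: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    reversible: bool = True


# ---------------------------------------------------------------------------
# microstates
# ---------------------------------------------------------------------------


def cluster_microstates(
    rc_values: list[np.ndarray] | np.ndarray,
    k: int,
    seed: int,
    origins: list[tuple[int, int]] | None = None,
) -> DiscreteTrajectorySet:
    """k-means microstates on scalar or vector reaction-coordinate values.

    ``rc_values`` is either one array or a list of per-segment arrays; every
    frame is assigned to its nearest center.  Centers are relabeled in
    ascending order of their first coordinate so state indices are
    deterministic and profile tables come out sorted.
    """
    if isinstance(rc_values, np.ndarray) and rc_values.ndim <= 2:
        segs = [rc_values]
    else:
        segs = list(rc_values)
    segs = [np.asarray(s, dtype=float) for s in segs]
    segs = [s[:, None] if s.ndim == 1 else s for s in segs]
    data = np.vstack(segs)
    n_distinct = np.unique(data, axis=0).shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct values")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, max_iter=500, tol=1e-6,
        random_state=seed,
    ).fit(data)
    order = np.lexsort(km.cluster_centers_.T[::-1])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    centers = km.cluster_centers_[order]
    labels = relabel[km.labels_]
    out, at = [], 0
    for s in segs:
        out.append(labels[at : at + len(s)])
        at += len(s)
    return DiscreteTrajectorySet(out, n_states=k, centers=centers, origins=origins)


# ---------------------------------------------------------------------------
# counting and estimation
# ---------------------------------------------------------------------------


def count_transitions(dtrajs: DiscreteTrajectorySet, lag: int) -> np.ndarray:
    """Sliding-window transition counts at the given lag.

    Every ordered pair (s_t, s_{t+lag}) inside the same segment increments
    the count matrix; segments shorter than the lag contribute nothing and
    no pair ever crosses a segment boundary.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n = dtrajs.n_states
    counts = np.zeros((n, n), dtype=float)
    for s in dtrajs.segments:
        if s.size > lag:
            np.add.at(counts, (s[:-lag], s[lag:]), 1.0)
    return counts


def largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """Largest set of states connected under the symmetrized count graph.

    Connectivity is judged on C + C^T (any observed transition links two
    states), then states left without outgoing counts inside the set are
    dropped iteratively so every row of the restricted matrix is
    normalizable.
    """
    counts = np.asarray(counts, dtype=float)
    sym = counts + counts.T
    n_comp, labels = connected_components(csr_matrix(sym > 0), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    # among equally large components prefer the one with more total counts
    best, best_key = 0, (-1.0, -1.0)
    for c in range(n_comp):
        members = labels == c
        key = (float(sizes[c]), float(counts[members][:, members].sum()))
        if key > best_key:
            best, best_key = c, key
    active = np.flatnonzero(labels == best)
    while active.size:
        sub = counts[np.ix_(active, active)]
        alive = sub.sum(axis=1) > 0
        if alive.all():
            break
        active = active[alive]
    return active


def estimate_T(counts: np.ndarray, reversible: bool = True) -> np.ndarray:
    """Row-stochastic transition matrix from a count matrix.

    Non-reversible: the maximum-likelihood row normalization
    T_ij = c_ij / sum_j c_ij.  Reversible: the symmetrized-count estimator
    T_ij = (c_ij + c_ji) / sum_j (c_ij + c_ji), which satisfies detailed
    balance exactly with pi proportional to the row sums of C + C^T.

    Estimation is restricted to the largest strongly connected set; dropped
    states are logged.  The caller receives the restricted matrix (use
    :func:`largest_connected_set` to recover the index mapping).
    """
    counts = np.asarray(counts, dtype=float)
    active = largest_connected_set(counts)
    if active.size == 0 or counts[np.ix_(active, active)].sum() == 0:
        raise ValueError("empty connected set: no transitions to estimate from")
    if active.size < counts.shape[0]:
        dropped = sorted(set(range(counts.shape[0])) - set(active.tolist()))
        logger.warning("dropping %d disconnected microstates: %s", len(dropped), dropped)
    c = counts[np.ix_(active, active)]
    if reversible:
        c = c + c.T
    rows = c.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("state in connected set has no outgoing counts")
    return c / rows[:, None]


def implied_timescales(T: np.ndarray, lag: int) -> np.ndarray:
    """Relaxation times t_i = -lag / ln lambda_i for the non-stationary modes.

    Eigenvalues are sorted by descending modulus and the stationary one
    (lambda_1 = 1) is excluded.  Complex or non-positive eigenvalues have no
    timescale and are reported as NaN; eigenvalues at exactly 1 (degenerate
    stationary modes) give infinity.
    """
    T = np.asarray(T, dtype=float)
    ev = np.linalg.eigvals(T)
    ev = ev[np.argsort(-np.abs(ev))][1:]
    ts = np.full(ev.size, np.nan)
    for i, lam in enumerate(ev):
        if abs(lam.imag) > 1e-12:
            continue
        lr = lam.real
        if lr >= 1.0 - 1e-15:
            ts[i] = np.inf
        elif lr > 0.0:
            ts[i] = -lag / np.log(lr)
    return ts


def select_lag(
    dtrajs: DiscreteTrajectorySet,
    lag_grid: list[int] | tuple[int, ...],
    plateau_tol: float = 0.2,
    reversible: bool = True,
) -> int:
    """Smallest lag at which the slowest implied timescale has plateaued.

    The plateau test compares t_slow at each grid lag with the next grid
    point (relative change < ``plateau_tol``).  If no lag plateaus, the
    largest grid lag is returned with a warning.
    """
    lags = sorted(int(l) for l in lag_grid)
    if not lags:
        raise ValueError("empty lag grid")
    if any(b <= a for a, b in zip(lags, lags[1:])):
        raise ValueError("lag grid must be strictly increasing")
    slow = []
    for lag in lags:
        try:
            T = estimate_T(count_transitions(dtrajs, lag), reversible=reversible)
            ts = implied_timescales(T, lag)
            finite = ts[np.isfinite(ts)]
            slow.append(float(finite.max()) if finite.size else np.nan)
        except ValueError:
            slow.append(np.nan)
    if all(np.isnan(s) for s in slow):
        raise ValueError("all lags yield undefined implied timescales")
    if len(lags) == 1:
        return lags[0]
    for i in range(len(lags) - 1):
        a, b = slow[i], slow[i + 1]
        if np.isnan(a) or np.isnan(b) or b == 0:
            continue
        if abs(a - b) / abs(b) < plateau_tol:
            return lags[i]
    logger.warning(
        "implied timescales did not plateau on the lag grid %s; using the largest", lags
    )
    return lags[-1]


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Left eigenvector of eigenvalue 1, normalized to a probability vector.

    Raises
    ------
    ValueError
        If T is reducible, naming the disconnected blocks.
    """
    T = np.asarray(T, dtype=float)
    n_comp, labels = connected_components(
        csr_matrix(T > 0), directed=True, connection="strong"
    )
    if n_comp > 1:
        blocks = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ValueError(f"transition matrix is reducible; blocks: {blocks}")
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def free_energy_profile(pi: np.ndarray, kBT: float = 1.0) -> np.ndarray:
    """F_i = -kBT ln(pi_i / max_k pi_k); zero at the most populated state.

    Zero-probability states get +inf.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.size == 0 or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be a probability vector")
    top = pi.max()
    with np.errstate(divide="ignore"):
        return np.where(pi > 0, -kBT * np.log(np.where(pi > 0, pi, 1.0) / top), np.inf)


# ---------------------------------------------------------------------------
# end-to-end profile pipeline
# ---------------------------------------------------------------------------


def _model_from_dtrajs(
    dtrajs: DiscreteTrajectorySet,
    lag_grid,
    kBT: float,
    plateau_tol: float,
    reversible: bool,
) -> TransitionModel:
    if dtrajs.n_states == 1:
        return TransitionModel(
            lag=int(sorted(lag_grid)[0]), counts=np.array([[1.0]]),
            T=np.array([[1.0]]), pi=np.array([1.0]), timescales=np.zeros(0),
            free_energy=np.array([0.0]), kBT=kBT, centers=dtrajs.centers,
            active=np.array([0]), reversible=reversible,
        )
    lag = select_lag(dtrajs, lag_grid, plateau_tol=plateau_tol, reversible=reversible)
    counts = count_transitions(dtrajs, lag)
    active = largest_connected_set(counts)
    T = estimate_T(counts, reversible=reversible)
    pi = stationary_distribution(T)
    return TransitionModel(
        lag=lag,
        counts=counts[np.ix_(active, active)],
        T=T,
        pi=pi,
        timescales=implied_timescales(T, lag),
        free_energy=free_energy_profile(pi, kBT),
        kBT=kBT,
        centers=dtrajs.centers[active],
        active=active,
        reversible=reversible,
    )


def profile_from_rc_segments(
    segments: list[np.ndarray],
    k: int = 30,
    lag_grid=(1, 2, 5, 10),
    kBT: float = 1.0,
    seed: int = 0,
    plateau_tol: float = 0.2,
    reversible: bool = True,
    origins: list[tuple[int, int]] | None = None,
) -> tuple[TransitionModel, pd.DataFrame]:
    """Full MSM pipeline on per-segment reaction-coordinate series.

    Clusters into at most ``k`` microstates (clamped to the number of
    distinct values), selects the lag on the implied-timescale plateau,
    estimates a reversible transition matrix, and returns the model plus a
    table of (rc_center, free_energy) sorted by center.
    """
    segs = [np.asarray(s, dtype=float) for s in segments]
    data = np.concatenate([s.reshape(len(s), -1) for s in segs])
    k_eff = min(k, np.unique(data, axis=0).shape[0])
    dtrajs = cluster_microstates(segs, k_eff, seed=seed, origins=origins)
    model = _model_from_dtrajs(dtrajs, lag_grid, kBT, plateau_tol, reversible)
    table = pd.DataFrame(
        {
            "rc_center": model.centers[:, 0],
            "free_energy": model.free_energy,
            "stationary_probability": model.pi,
        }
    ).sort_values("rc_center", ignore_index=True)
    return model, table


def profile_along_rc(
    result,
    rc: RCSpec | None = None,
    k: int = 30,
    lag_grid=(1, 2, 5, 10),
    kBT: float = 1.0,
    seed: int = 0,
    plateau_tol: float = 0.2,
) -> tuple[TransitionModel, pd.DataFrame]:
    """Free-energy profile along a reaction coordinate of a cascade run.

    Evaluates the coordinate on every stored frame, segment by segment
    (one segment per cycle/replica pair, never concatenated), then runs the
    MSM pipeline.  Requires a run of at least 2 cycles.
    """
    if result.n_cycles < 2:
        raise ValueError("profile_along_rc requires a run of >= 2 cycles")
    rc = rc if rc is not None else result.config.rc
    segments, origins = [], []
    for origin, snaps in result.segments():
        vals = np.array([
            s.rc if (rc is result.config.rc and s.rc is not None)
            else float(evaluate_rc_pool([s], rc)[0])
            for s in snaps
        ])
        segments.append(vals)
        origins.append(origin)
    return profile_from_rc_segments(
        segments, k=k, lag_grid=lag_grid, kBT=kBT, seed=seed,
        plateau_tol=plateau_tol, origins=origins,
    )
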