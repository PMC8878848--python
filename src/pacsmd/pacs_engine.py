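"""The parallel-cascade-selection cycle engine.

One cycle: run N short stochastic segments, pool the N x M recorded
snapshots, rank them by the reaction coordinate (ascending), select the top
N as seeds for the next cycle, regenerate their velocities from the
Maxwell-Boltzmann distribution, and repeat until the best snapshot drops
below the cutoff, the pooled RC distribution stops changing, or the cycle
budget runs out.  With the d_COM coordinate and a multi-copy ligand
environment this is the ligand-binding variant (LB-PaCS); with an RMSD-to-
product coordinate it is the targeted variant (t-PaCS).  The loop is
engine-agnostic: any backend satisfying :class:`EngineAdapter` can be driven.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .model_system import (
    SITE_COPY_ID,
    DynamicsParams,
    Snapshot,
    SystemState,
    ToyPotentialSpec,
    arrange_ligand_copies,
    draw_mb_velocities,
    run_segment,
)
from .reaction_coordinates import (
    AtomSelection,
    RCSpec,
    center_of_mass,
    d_com_all_copies,
    evaluate_rc_pool,
    selection_from_copy_ids,
)

__all__ = [
    "CONTINUE",
    "CUTOFF",
    "CONVERGED",
    "MAX_CYCLES",
    "SamplingConfig",
    "CycleRecord",
    "PacsResult",
    "EngineAdapter",
    "ToyEngineAdapter",
    "derive_seed",
    "rank_and_select",
    "check_termination",
    "detect_aggregation",
    "run_pacs",
    "trace_binding_paths",
]

logger = logging.getLogger(__name__)

CONTINUE = "continue"
CUTOFF = "cutoff"
CONVERGED = "converged"
MAX_CYCLES = "max_cycles"

_PURPOSES = {"arrange": 0, "velocity": 1, "segment": 2, "reset": 3, "trial": 4}


def derive_seed(root_seed: int, purpose: str, *indices: int) -> int:
    """Stable stream seed for (run seed, purpose, cycle, replica, ...).

    Uses a :class:`numpy.random.SeedSequence` spawn key, so streams are
    reproducible independently of execution order and replica count.
    """
    key = (_PURPOSES[purpose],) + tuple(int(i) for i in indices)
    ss = np.random.SeedSequence(int(root_seed), spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SamplingConfig:
    """All cycle-engine parameters.

    ``n_replicas`` is the protocol's N (segments per cycle),
    ``frames_per_segment`` its M; defaults are N = M = 10.  ``cutoff`` terminates the run once the
    best RC value of a cycle drops below it (``None`` disables).  The
    distribution-convergence criterion compares window-averaged RC
    histograms over ``convergence_window`` cycles with L1 tolerance
    ``convergence_tol`` (0 disables).
    """

    n_replicas: int = 10
    frames_per_segment: int = 10
    cutoff: float | None = None
    max_cycles: int = 50
    seed: int = 0
    rc: RCSpec | None = None
    convergence_window: int = 5
    convergence_tol: float = 0.05
    n_rc_bins: int = 20
    aggregation_threshold: float = 1.0
    aggregation_policy: str = "none"
    rank_granularity: str = "snapshot"
    pool_scope: str = "cycle"

    def __post_init__(self) -> None:
        if self.n_replicas < 1 or self.frames_per_segment < 1 or self.max_cycles < 1:
            raise ValueError("n_replicas, frames_per_segment, max_cycles must be >= 1")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be > 0 (or None to disable)")
        if self.aggregation_policy not in ("none", "reset"):
            raise ValueError("aggregation_policy must be 'none' or 'reset'")
        if self.rank_granularity not in ("snapshot", "copy"):
            raise ValueError("rank_granularity must be 'snapshot' or 'copy'")
        if self.pool_scope not in ("cycle", "global"):
            raise ValueError("pool_scope must be 'cycle' or 'global'")


@dataclass
class CycleRecord:
    """Per-cycle summary: pooled RC values and the selected seeds."""

    cycle_index: int
    ids: list[tuple[int, int, int]]
    rc_values: np.ndarray
    selected: list[tuple[int, int, int]]
    best_rc_this_cycle: float
    best_rc_so_far: float


@dataclass
class PacsResult:
    """Outcome of a cascade-selection run."""

    cycles: list[CycleRecord]
    termination_reason: str
    snapshots: dict[tuple[int, int, int], Snapshot]
    config: SamplingConfig
    binding_paths: list[list[tuple[int, int, int]]] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def segments(self) -> list[tuple[tuple[int, int], list[Snapshot]]]:
        """Snapshots grouped by (cycle, replica) in frame order."""
        groups: dict[tuple[int, int], list[Snapshot]] = {}
        for sid in sorted(self.snapshots):
            s = self.snapshots[sid]
            groups.setdefault((s.cycle, s.replica), []).append(s)
        return sorted(groups.items())


@runtime_checkable
class EngineAdapter(Protocol):
    """Contract a dynamics backend must honor to be driven by the loop.

    ``propagate`` must return exactly M snapshots and be deterministic given
    its seed; ``regenerate_velocities`` must draw fresh Maxwell-Boltzmann
    velocities without touching positions.
    """

    def propagate(self, snapshot: Snapshot, seed: int) -> list[Snapshot]: ...

    def regenerate_velocities(self, snapshot: Snapshot, seed: int) -> Snapshot: ...


class ToyEngineAdapter:
    """Drives the built-in Langevin engine.

    ``arrange_params`` (dict with r_min, r_max, min_separation) enables the
    aggregation-reset procedure, which re-places all but the best-placed
    ligand copy into the arrangement shell.
    """

    def __init__(
        self,
        spec: ToyPotentialSpec,
        params: DynamicsParams,
        arrange_params: dict | None = None,
    ):
        self.spec = spec
        self.params = params
        self.arrange_params = arrange_params

    def propagate(self, snapshot: Snapshot, seed: int) -> list[Snapshot]:
        return run_segment(snapshot.state, self.spec, self.params, seed)

    def regenerate_velocities(self, snapshot: Snapshot, seed: int) -> Snapshot:
        st = snapshot.state.copy()
        st.velocities = draw_mb_velocities(st.masses, self.params.temperature, seed)
        st.velocities[st.copy_id < 0] = 0.0
        return dataclasses.replace(snapshot, state=st)

    def reset_copies(self, snapshot: Snapshot, seed: int) -> Snapshot:
        """Re-arrange all ligand copies except the one closest to the site."""
        if self.arrange_params is None:
            raise RuntimeError("aggregation reset requires arrange_params")
        st = snapshot.state
        sel = selection_from_copy_ids(st.copy_id)
        best = int(np.argmin(d_com_all_copies(st.positions, sel)))
        fresh = arrange_ligand_copies(
            self.spec,
            n_copies=sel.n_copies,
            seed=seed,
            temperature=self.params.temperature,
            **self.arrange_params,
        )
        new = st.copy()
        for k, idx in st.copy_indices().items():
            if k == best:
                continue
            new.positions[idx] = fresh.positions[fresh.copy_id == k]
        return dataclasses.replace(snapshot, state=new)


# ---------------------------------------------------------------------------
# selection, termination, aggregation
# ---------------------------------------------------------------------------


def rank_and_select(
    pool: list[tuple[tuple[int, int, int], float]], n_select: int
) -> list[tuple[int, int, int]]:
    """Ids of the ``n_select`` smallest-RC snapshots, ascending.

    Ties break deterministically by (cycle, replica, frame).  If the pool is
    smaller than ``n_select``, ids recycle round-robin in rank order so that
    exactly ``n_select`` seeds are returned.
    """
    if not pool:
        raise ValueError("empty selection pool")
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    ranked = sorted(pool, key=lambda e: (e[1],) + tuple(e[0]))
    ids = [sid for sid, _ in ranked]
    if len(ids) >= n_select:
        return ids[:n_select]
    return [ids[i % len(ids)] for i in range(n_select)]


def _window_histogram(
    records: list[CycleRecord], bins: np.ndarray
) -> np.ndarray:
    pooled = np.concatenate([r.rc_values for r in records])
    h, _ = np.histogram(pooled, bins=bins)
    total = h.sum()
    return h / total if total else h.astype(float)


def check_termination(history: list[CycleRecord], config: SamplingConfig) -> str:
    """Decide whether to stop: cutoff, distribution convergence, or budget.

    The convergence criterion compares the fixed-bin RC histograms averaged
    over the last ``convergence_window`` cycles against the preceding window
    (L1 distance); bins span [0, max RC of the first cycle].
    """
    if not history:
        raise ValueError("history must be non-empty")
    last = history[-1]
    if config.cutoff is not None and last.best_rc_this_cycle < config.cutoff:
        return CUTOFF
    w = config.convergence_window
    if config.convergence_tol > 0 and w >= 1 and len(history) >= 2 * w:
        hi = max(float(history[0].rc_values.max()), 1e-12)
        bins = np.linspace(0.0, hi, config.n_rc_bins + 1)
        recent = _window_histogram(history[-w:], bins)
        previous = _window_histogram(history[-2 * w : -w], bins)
        if np.abs(recent - previous).sum() < config.convergence_tol:
            return CONVERGED
    if last.cycle_index + 1 >= config.max_cycles:
        return MAX_CYCLES
    return CONTINUE


def detect_aggregation(
    snapshot: Snapshot | SystemState,
    threshold: float,
    selection: AtomSelection | None = None,
) -> list[list[int]]:
    """Single-linkage clusters of ligand copies closer than ``threshold``.

    Returns the clusters as lists of copy labels; any cluster of size >= 2
    means the copies have aggregated.
    """
    state = snapshot.state if isinstance(snapshot, Snapshot) else snapshot
    if selection is None:
        selection = selection_from_copy_ids(state.copy_id)
    n = selection.n_copies
    if n < 2:
        raise ValueError("aggregation detection needs >= 2 ligand copies")
    coms = np.array(
        [
            center_of_mass(state.positions[ix], selection._w(ix))
            for ix in selection.ligand_indices
        ]
    )
    d = np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=-1)
    adj = csr_matrix((d < threshold) & ~np.eye(n, dtype=bool))
    n_comp, labels = connected_components(adj, directed=False)
    return [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]


# ---------------------------------------------------------------------------
# the cycle loop
# ---------------------------------------------------------------------------

Observer = Callable[[CycleRecord, list[Snapshot]], None]


def run_pacs(
    config: SamplingConfig,
    engine: EngineAdapter,
    initial: SystemState,
    observer: Observer | None = None,
) -> PacsResult:
    """Run the full cascade-selection protocol from a reactant state.

    Cycle 0 seeds all N replicas from ``initial``; each later cycle reseeds
    from the top-N snapshots of the previous cycle's pool.  Velocities are
    always regenerated from the Maxwell-Boltzmann distribution at segment
    start.  Fully reproducible from ``config.seed``.  ``observer`` (if
    given) is called once per completed cycle with the record and the new
    snapshots, enabling streaming output.
    """
    if config.rc is None:
        raise ValueError("config.rc must be set")
    return _run_cycles(config, engine, seeds=None, history=[], snapshots={},
                       start_cycle=0, observer=observer, initial=initial)


def _run_cycles(
    config: SamplingConfig,
    engine: EngineAdapter,
    seeds: list[Snapshot] | None,
    history: list[CycleRecord],
    snapshots: dict[tuple[int, int, int], Snapshot],
    start_cycle: int,
    observer: Observer | None,
    initial: SystemState | None = None,
) -> PacsResult:
    """Shared driver for fresh runs and resumed runs."""
    n = config.n_replicas
    reason = MAX_CYCLES
    global_pool: list[tuple[tuple[int, int, int], float]] = [
        (sid, s.rc) for sid, s in snapshots.items() if s.rc is not None
    ]
    best_so_far = history[-1].best_rc_so_far if history else np.inf
    for cycle in range(start_cycle, config.max_cycles):
        new_snaps: list[Snapshot] = []
        for r in range(n):
            if seeds is None:
                seed_state, parent = initial, None
            else:
                seed_snap = seeds[r]
                seed_state, parent = seed_snap.state, seed_snap.id
            snap = Snapshot(state=seed_state, cycle=cycle, replica=r, parent=parent)
            if (
                config.aggregation_policy == "reset"
                and len(seed_state.copy_indices()) >= 2
            ):
                clusters = detect_aggregation(snap, config.aggregation_threshold)
                if any(len(c) >= 2 for c in clusters):
                    logger.info(
                        "cycle %d replica %d: aggregated clusters %s, resetting copies",
                        cycle, r, [c for c in clusters if len(c) >= 2],
                    )
                    snap = engine.reset_copies(
                        snap, derive_seed(config.seed, "reset", cycle, r)
                    )
            snap = engine.regenerate_velocities(
                snap, derive_seed(config.seed, "velocity", cycle, r)
            )
            try:
                frames = engine.propagate(
                    snap, derive_seed(config.seed, "segment", cycle, r)
                )
            except Exception as exc:
                raise RuntimeError(
                    f"engine failure at cycle {cycle}, replica {r}: {exc}"
                ) from exc
            if len(frames) != config.frames_per_segment:
                raise RuntimeError(
                    f"engine returned {len(frames)} frames at cycle {cycle}, "
                    f"replica {r}; expected {config.frames_per_segment}"
                )
            for f, s in enumerate(frames):
                s.cycle, s.replica, s.frame, s.parent = cycle, r, f, parent
                snapshots[s.id] = s
                new_snaps.append(s)
        rc_vals = evaluate_rc_pool(new_snaps, config.rc)
        for s, v in zip(new_snaps, rc_vals):
            s.rc = float(v)
        cycle_pool = [(s.id, s.rc) for s in new_snaps]
        global_pool.extend(cycle_pool)
        pool = global_pool if config.pool_scope == "global" else cycle_pool
        if config.rank_granularity == "copy" and config.rc.kind == "d_com":
            sel_pool = []
            for sid, _ in cycle_pool:
                st = snapshots[sid].state
                per_copy = d_com_all_copies(st.positions, config.rc.selection)
                sel_pool.extend((sid, float(v)) for v in per_copy)
            selected_raw = rank_and_select(sel_pool, n)
        else:
            selected_raw = rank_and_select(pool, n)
        best = float(rc_vals.min())
        best_so_far = min(best_so_far, best)
        record = CycleRecord(
            cycle_index=cycle,
            ids=[s.id for s in new_snaps],
            rc_values=rc_vals,
            selected=selected_raw,
            best_rc_this_cycle=best,
            best_rc_so_far=best_so_far,
        )
        history.append(record)
        if observer is not None:
            observer(record, new_snaps)
        verdict = check_termination(history, config)
        if verdict != CONTINUE:
            reason = verdict
            break
        seeds = [snapshots[sid] for sid in record.selected]
    result = PacsResult(
        cycles=history,
        termination_reason=reason,
        snapshots=snapshots,
        config=config,
    )
    if config.cutoff is not None:
        result.binding_paths = trace_binding_paths(result)
    return result


def trace_binding_paths(result: PacsResult) -> list[list[tuple[int, int, int]]]:
    """Ancestor chain of every final-cycle snapshot below the cutoff.

    Each chain runs from a cycle-0 snapshot to the terminal bound snapshot,
    strictly increasing in cycle index (parents live one cycle earlier).

    Raises
    ------
    KeyError
        If a parent link points outside the trajectory archive.
    """
    cutoff = result.config.cutoff
    if cutoff is None:
        raise ValueError("tracing binding paths requires a cutoff")
    if not result.cycles:
        return []
    last = result.cycles[-1]
    paths: list[list[tuple[int, int, int]]] = []
    for sid, rc in zip(last.ids, last.rc_values):
        if rc >= cutoff:
            continue
        chain = [sid]
        parent = result.snapshots[sid].parent
        while parent is not None:
            if parent not in result.snapshots:
                raise KeyError(
                    f"broken parent link: {parent} missing from trajectory archive"
                )
            chain.append(parent)
            parent = result.snapshots[parent].parent
        chain.reverse()
        paths.append(chain)
    return paths
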