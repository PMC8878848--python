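"""Reaction coordinates and snapshot-scoring functions.

The ranking input of the cascade-selection loop: the ligand-to-binding-site
center-of-mass distance d_COM (the ligand-binding coordinate), superposition
RMSD to a product structure (the targeted-selection coordinate), the
distance-matrix difference score Delta, the radius of gyration, and weighted
composite scores built from any of these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .model_system import SITE_COPY_ID, Snapshot, SystemState

__all__ = [
    "AtomSelection",
    "RCSpec",
    "selection_from_copy_ids",
    "center_of_mass",
    "d_com",
    "d_com_all_copies",
    "rmsd",
    "delta_matrix_score",
    "radius_of_gyration",
    "evaluate_rc",
    "evaluate_rc_pool",
]

RC_KINDS = ("d_com", "rmsd_to_product", "delta_matrix", "radius_of_gyration", "composite")


@dataclass
class AtomSelection:
    """Particle index sets defining the ligand copies and the binding site.

    ``weights`` (optional) are per-particle positive weights aligned with the
    full coordinate array; ``None`` means unit weights, matching the
    carbon-atom COM convention (mass weighting is the caller's opt-in).
    """

    ligand_indices: list[np.ndarray]
    site_indices: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ligand_indices = [
            np.asarray(ix, dtype=int).reshape(-1) for ix in self.ligand_indices
        ]
        self.site_indices = np.asarray(self.site_indices, dtype=int).reshape(-1)
        if not self.ligand_indices or any(ix.size == 0 for ix in self.ligand_indices):
            raise ValueError("every ligand copy selection must be non-empty")
        if self.site_indices.size == 0:
            raise ValueError("site selection must be non-empty")
        lig = np.concatenate(self.ligand_indices)
        if np.intersect1d(lig, self.site_indices).size:
            raise ValueError("ligand and site selections must be disjoint")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")

    @property
    def n_copies(self) -> int:
        return len(self.ligand_indices)

    def _w(self, idx: np.ndarray) -> np.ndarray | None:
        return None if self.weights is None else self.weights[idx]


def selection_from_copy_ids(copy_id: np.ndarray) -> AtomSelection:
    """Build the natural selection for a toy-engine state.

    Ligand copies are the groups of equal non-negative ``copy_id``; the site
    is the frozen marker particle(s).
    """
    copy_id = np.asarray(copy_id, dtype=int)
    site = np.flatnonzero(copy_id == SITE_COPY_ID)
    labels = sorted(set(copy_id[copy_id >= 0].tolist()))
    if site.size == 0:
        raise ValueError("state has no site marker particle")
    if not labels:
        raise ValueError("state has no ligand copies")
    return AtomSelection([np.flatnonzero(copy_id == k) for k in labels], site)


@dataclass
class RCSpec:
    """Declarative description of a reaction coordinate.

    ``reference`` (a coordinate set of the product/bound structure) is
    required for ``rmsd_to_product`` and ``delta_matrix``.  For multi-copy
    snapshots, ``copy_reduction`` collapses per-copy values to one score per
    snapshot; the default ``"min"`` means any copy binding counts.
    ``components`` holds (RCSpec, weight) pairs for ``composite``.
    """

    kind: str
    selection: AtomSelection | None = None
    reference: np.ndarray | None = None
    components: list[tuple["RCSpec", float]] = field(default_factory=list)
    copy_reduction: str = "min"
    superpose: bool = True

    def __post_init__(self) -> None:
        if self.kind not in RC_KINDS:
            raise ValueError(f"unknown rc kind {self.kind!r}; expected one of {RC_KINDS}")
        if self.kind in ("rmsd_to_product", "delta_matrix"):
            if self.reference is None:
                raise ValueError(f"{self.kind} requires a reference structure")
            self.reference = np.asarray(self.reference, dtype=float).reshape(-1, 3)
        elif self.reference is not None:
            raise ValueError(f"{self.kind} does not take a reference")
        if self.kind == "composite":
            if not self.components:
                raise ValueError("composite requires components")
            w = np.array([wk for _, wk in self.components], dtype=float)
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("composite weights must be >= 0 and not all zero")
        if self.copy_reduction not in ("min", "mean"):
            raise ValueError("copy_reduction must be 'min' or 'mean'")


# ---------------------------------------------------------------------------
# elementary coordinates
# ---------------------------------------------------------------------------


def center_of_mass(coords: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted centroid sum(w_i x_i) / sum(w_i)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValueError("empty selection")
    if weights is None:
        return coords.mean(axis=0)
    weights = np.asarray(weights, dtype=float).reshape(-1)
    if weights.size != coords.shape[0]:
        raise ValueError("weights length mismatch")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return weights @ coords / weights.sum()


def d_com(coords: np.ndarray, selection: AtomSelection, copy: int) -> float:
    """COM distance between one ligand copy and the binding site."""
    if not 0 <= copy < selection.n_copies:
        raise ValueError(f"copy {copy} not in selection (n_copies={selection.n_copies})")
    coords = np.asarray(coords, dtype=float)
    lig = selection.ligand_indices[copy]
    c_lig = center_of_mass(coords[lig], selection._w(lig))
    c_site = center_of_mass(coords[selection.site_indices], selection._w(selection.site_indices))
    return float(np.linalg.norm(c_lig - c_site))


def d_com_all_copies(coords: np.ndarray, selection: AtomSelection) -> np.ndarray:
    """d_COM of every ligand copy, in copy order."""
    return np.array([d_com(coords, selection, k) for k in range(selection.n_copies)])


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation, optionally after Kabsch superposition.

    With ``superpose=True`` both sets are centered and the optimal proper
    rotation (least-squares, Kabsch) is applied before the RMSD; the result
    is then invariant under any rigid motion of either set.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"point counts differ: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise ValueError("empty coordinate sets")
    if not superpose:
        return float(np.sqrt(((a - b) ** 2).sum() / a.shape[0]))
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(a.shape[0]))


def delta_matrix_score(
    coords: np.ndarray, reference: np.ndarray, indices: np.ndarray | None = None
) -> float:
    """Distance-matrix difference Delta = sum_{i<j} |A_ij - B_ij|.

    A and B are the pairwise-distance matrices of the selected atoms in the
    instantaneous and reference structures; each unordered pair is counted
    once (the double-sum convention would only rescale by 2).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if indices is not None:
        indices = np.asarray(indices, dtype=int).reshape(-1)
        coords = coords[indices]
        reference = reference[indices]
    if coords.shape[0] < 2:
        raise ValueError("delta_matrix_score needs at least 2 atoms")
    if coords.shape != reference.shape:
        raise ValueError("instantaneous/reference atom counts differ")
    return float(np.abs(pdist(coords) - pdist(reference)).sum())


def radius_of_gyration(coords: np.ndarray, weights: np.ndarray | None = None) -> float:
    """sqrt( sum w_i |x_i - COM|^2 / sum w_i )."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValueError("empty selection")
    com = center_of_mass(coords, weights)
    sq = ((coords - com) ** 2).sum(axis=1)
    if weights is None:
        return float(np.sqrt(sq.mean()))
    weights = np.asarray(weights, dtype=float).reshape(-1)
    return float(np.sqrt(weights @ sq / weights.sum()))


# ---------------------------------------------------------------------------
# dispatch and pool scoring
# ---------------------------------------------------------------------------


def _reduce(values: np.ndarray, rule: str) -> float:
    return float(values.min() if rule == "min" else values.mean())


def _evaluate_simple(coords: np.ndarray, spec: RCSpec) -> float:
    sel = spec.selection
    if sel is None:
        raise ValueError(f"{spec.kind} requires a selection")
    if spec.kind == "d_com":
        return _reduce(d_com_all_copies(coords, sel), spec.copy_reduction)
    if spec.kind == "radius_of_gyration":
        per_copy = np.array(
            [radius_of_gyration(coords[ix], sel._w(ix)) for ix in sel.ligand_indices]
        )
        return _reduce(per_copy, spec.copy_reduction)
    idx = np.concatenate([sel.site_indices] + list(sel.ligand_indices))
    if spec.kind == "rmsd_to_product":
        return rmsd(coords[idx], spec.reference, superpose=spec.superpose)
    if spec.kind == "delta_matrix":
        return delta_matrix_score(coords[idx], spec.reference)
    raise ValueError(f"cannot evaluate kind {spec.kind!r} without a pool")


def evaluate_rc(snapshot: Snapshot | SystemState, spec: RCSpec) -> float:
    """Score a single snapshot.

    Composites with a single component reduce to that component; composites
    with several components are evaluated as the weight-normalized mean of
    the raw component values (pool-level z-score normalization needs a pool
    — see :func:`evaluate_rc_pool`).
    """
    return float(evaluate_rc_pool([snapshot], spec)[0])


def evaluate_rc_pool(
    snapshots: list[Snapshot | SystemState], spec: RCSpec
) -> np.ndarray:
    """Score every snapshot of a pool.

    For multi-component composites the components are z-scored over the pool
    before weighting (so incommensurate units do not dominate the ranking);
    single-component composites are the identity, and pools of one snapshot
    fall back to raw values.
    """
    coords = [
        (s.state.positions if isinstance(s, Snapshot) else s.positions)
        for s in snapshots
    ]
    if spec.kind != "composite":
        return np.array([_evaluate_simple(c, spec) for c in coords])
    if len(spec.components) == 1:
        sub, _ = spec.components[0]
        return evaluate_rc_pool(snapshots, sub)
    comps = np.stack([evaluate_rc_pool(snapshots, sub) for sub, _ in spec.components])
    weights = np.array([w for _, w in spec.components], dtype=float)
    if len(snapshots) > 1:
        mu = comps.mean(axis=1, keepdims=True)
        sd = comps.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        comps = (comps - mu) / sd
    return weights @ comps / weights.sum()
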