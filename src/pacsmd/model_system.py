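"""Toy physical substrate for ligand-binding path sampling.

A static "protein" is represented by a radial funnel potential: an attractive
Gaussian well at the binding-site center, a soft-core wall standing in for the
excluded protein core, and a harmonic outer wall confining the search volume
(a crude mimic of a solvent box).  Mobile "ligand copies" — single particles
or near-rigid hexagonal rings — diffuse in this landscape under Langevin
dynamics (BAOAB splitting) and repel each other through a compact-support
soft pair potential so that a concentrated multi-copy environment does not
aggregate.

Reduced units throughout: k_B*T = 1 defines the energy scale, particle mass
defaults to 1, and the length unit is Angstrom-like but carries no force-field
meaning.

The integrator and velocity draws are deterministic given an integer seed;
every stochastic stream is a distinct ``numpy.random.Generator``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SITE_COPY_ID",
    "ToyPotentialSpec",
    "SystemState",
    "DynamicsParams",
    "Snapshot",
    "PackingError",
    "IntegrationError",
    "draw_mb_velocities",
    "arrange_ligand_copies",
    "toy_energy",
    "toy_force",
    "radial_potential",
    "run_segment",
    "run_plain_md",
]

#: copy_id assigned to the static binding-site marker particle
SITE_COPY_ID = -1


class PackingError(RuntimeError):
    """Raised when random ligand arrangement cannot satisfy its constraints."""


class IntegrationError(RuntimeError):
    """Raised when Langevin integration produces non-finite coordinates."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ToyPotentialSpec:
    """Parameters of the funnel landscape and of the ligand copies.

    Parameters
    ----------
    site_center : (3,) array-like
        Position of the binding site (reduced length units).
    well_depth : float
        Depth D of the attractive Gaussian well, U_well = -D exp(-r^2/2s^2).
    well_width : float
        Gaussian width s of the well.
    excluded_radius : float
        Radius of the soft protein core around the site center; inside it a
        harmonic half-wall of stiffness ``core_strength`` pushes outward.
    confinement_radius : float
        Radius of the outer spherical wall; beyond it a harmonic half-wall of
        stiffness ``confinement_strength`` pushes inward.
    copy_repulsion_strength, copy_repulsion_range : float
        Compact-support pair repulsion between particles belonging to
        distinct ligand copies, U = eps (1 - d/R)^2 for d < R, zero beyond.
        This is the "weakly repulsive intermolecular interaction" that keeps
        a concentrated copy environment from aggregating.
    ligand_sites : int
        Sites per ligand copy; 1 for point ligands, >1 builds a near-rigid
        regular ring (for center-of-mass / gyration / distance-matrix
        coordinates on extended ligands).
    ligand_ring_radius : float
        Circumradius of the ring when ``ligand_sites > 1``.
    bond_strength : float
        Stiffness of the intra-copy elastic network holding the ring shape.
    """

    site_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    well_depth: float = 10.0
    well_width: float = 1.5
    excluded_radius: float = 2.0
    confinement_radius: float = 40.0
    copy_repulsion_strength: float = 5.0
    copy_repulsion_range: float = 2.0
    core_strength: float = 50.0
    confinement_strength: float = 5.0
    ligand_sites: int = 1
    ligand_ring_radius: float = 0.7
    bond_strength: float = 200.0

    def __post_init__(self) -> None:
        self.site_center = np.asarray(self.site_center, dtype=float).reshape(3)
        if self.well_width <= 0:
            raise ValueError("well_width must be positive")
        if not self.excluded_radius < self.confinement_radius:
            raise ValueError("excluded_radius must be < confinement_radius")
        for name in (
            "well_depth",
            "copy_repulsion_strength",
            "core_strength",
            "confinement_strength",
            "bond_strength",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.excluded_radius < 0 or self.copy_repulsion_range < 0:
            raise ValueError("radii must be >= 0")
        if self.ligand_sites < 1:
            raise ValueError("ligand_sites must be >= 1")


@dataclass
class SystemState:
    """Positions, velocities, masses and copy labels at one instant.

    ``copy_id`` assigns each particle to a ligand copy (0, 1, ...) or marks
    it as the static binding-site marker (``SITE_COPY_ID``).  Marker
    particles are frozen: they carry no thermal noise and never move.
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    copy_id: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        self.copy_id = np.asarray(self.copy_id, dtype=int).reshape(-1)
        n = self.positions.shape[0]
        if not (self.velocities.shape[0] == self.masses.size == self.copy_id.size == n):
            raise ValueError("positions/velocities/masses/copy_id lengths differ")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def mobile(self) -> np.ndarray:
        """Indices of non-frozen (ligand) particles."""
        return np.flatnonzero(self.copy_id >= 0)

    def copy_indices(self) -> dict[int, np.ndarray]:
        """Particle indices of each ligand copy, keyed by copy label."""
        labels = sorted(set(self.copy_id[self.copy_id >= 0].tolist()))
        return {k: np.flatnonzero(self.copy_id == k) for k in labels}

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            self.masses.copy(),
            self.copy_id.copy(),
        )


@dataclass
class DynamicsParams:
    """Langevin integration parameters.

    ``frames_per_segment`` is the number M of snapshots recorded per short
    segment; one frame is recorded every ``n_steps_per_frame`` BAOAB steps.
    """

    dt: float = 0.02
    temperature: float = 1.0
    friction: float = 1.0
    n_steps_per_frame: int = 10
    frames_per_segment: int = 10

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.n_steps_per_frame < 1 or self.frames_per_segment < 1:
            raise ValueError("step/frame counts must be >= 1")


@dataclass
class Snapshot:
    """A stored state plus provenance within a PaCS run.

    ``parent`` is the id of the snapshot this segment was seeded from
    (``None`` for cycle-0 segments started from the reactant); ``rc`` caches
    the reaction-coordinate value once evaluated.
    """

    state: SystemState
    cycle: int = 0
    replica: int = 0
    frame: int = 0
    parent: tuple[int, int, int] | None = None
    rc: float | None = None

    @property
    def id(self) -> tuple[int, int, int]:
        return (self.cycle, self.replica, self.frame)


# ---------------------------------------------------------------------------
# Maxwell-Boltzmann velocities and random arrangement
# ---------------------------------------------------------------------------


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_mb_velocities(
    masses: np.ndarray, temperature: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw Maxwell-Boltzmann velocities: each component ~ N(0, kT/m_i).

    At temperature 0 the result is exactly zero.  Deterministic given seed.
    """
    masses = np.asarray(masses, dtype=float).reshape(-1)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    rng = _as_rng(seed)
    sigma = np.sqrt(temperature / masses)[:, None]
    return rng.standard_normal((masses.size, 3)) * sigma


def _ring_offsets(m: int, radius: float) -> np.ndarray:
    """Vertices of a regular m-gon of given circumradius in the xy plane."""
    ang = 2.0 * np.pi * np.arange(m) / m
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(m)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def arrange_ligand_copies(
    spec: ToyPotentialSpec,
    n_copies: int,
    r_min: float,
    r_max: float,
    min_separation: float,
    seed: int | np.random.Generator,
    temperature: float = 1.0,
    include_site_marker: bool = True,
    max_tries: int = 10_000,
) -> SystemState:
    """Randomly arrange ligand copies in a shell around the binding site.

    Copy centers are drawn uniformly from the shell
    ``r_min <= |x - site_center| <= r_max`` by rejection sampling, subject to
    all pairwise center separations being at least ``min_separation``.
    Velocities are drawn from the Maxwell-Boltzmann distribution at
    ``temperature``.  Particle 0 is a frozen marker at the site center unless
    ``include_site_marker`` is False.

    Raises
    ------
    PackingError
        If the per-copy rejection budget ``max_tries`` is exhausted, naming
        the violated constraint.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if r_min < spec.excluded_radius:
        raise ValueError("r_min must be >= excluded_radius")
    if r_max > spec.confinement_radius:
        raise ValueError("r_max must be <= confinement_radius")
    if not 0 < r_min <= r_max:
        raise ValueError("need 0 < r_min <= r_max")
    rng = _as_rng(seed)

    centers: list[np.ndarray] = []
    for k in range(n_copies):
        placed = False
        for _ in range(max_tries):
            u = rng.random()
            r = (u * (r_max**3 - r_min**3) + r_min**3) ** (1.0 / 3.0)
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            cand = spec.site_center + r * v
            if all(np.linalg.norm(cand - c) >= min_separation for c in centers):
                centers.append(cand)
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place copy {k}: pairwise min_separation="
                f"{min_separation} unsatisfiable in shell [{r_min}, {r_max}] "
                f"after {max_tries} attempts"
            )

    pos_blocks: list[np.ndarray] = []
    ids: list[int] = []
    if include_site_marker:
        pos_blocks.append(spec.site_center[None, :])
        ids.append(SITE_COPY_ID)
    m = spec.ligand_sites
    base = _ring_offsets(m, spec.ligand_ring_radius) if m > 1 else np.zeros((1, 3))
    for k, c in enumerate(centers):
        offs = base @ _random_rotation(rng).T if m > 1 else base
        pos_blocks.append(c[None, :] + offs)
        ids.extend([k] * m)
    positions = np.vstack(pos_blocks)
    copy_id = np.array(ids, dtype=int)
    masses = np.ones(positions.shape[0])
    velocities = draw_mb_velocities(masses, temperature, rng)
    velocities[copy_id < 0] = 0.0
    return SystemState(positions, velocities, masses, copy_id)


# ---------------------------------------------------------------------------
# energy and forces
# ---------------------------------------------------------------------------


class _ForceField:
    """Precomputed interaction lists for a fixed particle layout.

    Forces are computed on the mobile sub-array only; the frozen site marker
    has no interactions (the funnel is anchored to ``spec.site_center``, not
    to the marker particle).
    """

    def __init__(self, spec: ToyPotentialSpec, copy_id: np.ndarray):
        self.spec = spec
        copy_id = np.asarray(copy_id, dtype=int)
        self.mobile = np.flatnonzero(copy_id >= 0)
        mob_ids = copy_id[self.mobile]
        nm = self.mobile.size
        ii, jj = np.triu_indices(nm, k=1)
        inter = mob_ids[ii] != mob_ids[jj]
        self.rep_i = ii[inter]
        self.rep_j = jj[inter]
        # intra-copy elastic network (multi-site copies only): rest lengths
        # are the chord distances of the regular ring
        self.bond_i = ii[~inter]
        self.bond_j = jj[~inter]
        if self.bond_i.size:
            order = np.zeros(nm, dtype=int)
            for k in np.unique(mob_ids):
                idx = np.flatnonzero(mob_ids == k)
                order[idx] = np.arange(idx.size)
            m = spec.ligand_sites
            d = np.abs(order[self.bond_i] - order[self.bond_j])
            d = np.minimum(d, m - d)
            self.bond_rest = 2.0 * spec.ligand_ring_radius * np.sin(np.pi * d / m)
        else:
            self.bond_rest = np.zeros(0)

    # -- energy -------------------------------------------------------------

    def energy(self, xm: np.ndarray) -> float:
        """Potential energy of mobile coordinates ``xm`` (nm, 3)."""
        s = self.spec
        dx = xm - s.site_center
        r = np.linalg.norm(dx, axis=1)
        u = 0.0
        if s.well_depth > 0:
            u -= s.well_depth * np.exp(-(r**2) / (2.0 * s.well_width**2)).sum()
        if s.excluded_radius > 0:
            pen = np.maximum(s.excluded_radius - r, 0.0)
            u += 0.5 * s.core_strength * (pen**2).sum()
        out = np.maximum(r - s.confinement_radius, 0.0)
        u += 0.5 * s.confinement_strength * (out**2).sum()
        if self.rep_i.size and s.copy_repulsion_strength > 0:
            d = np.linalg.norm(xm[self.rep_i] - xm[self.rep_j], axis=1)
            inside = d < s.copy_repulsion_range
            if inside.any():
                t = 1.0 - d[inside] / s.copy_repulsion_range
                u += s.copy_repulsion_strength * (t**2).sum()
        if self.bond_i.size:
            d = np.linalg.norm(xm[self.bond_i] - xm[self.bond_j], axis=1)
            u += 0.5 * s.bond_strength * ((d - self.bond_rest) ** 2).sum()
        return float(u)

    # -- force --------------------------------------------------------------

    def force(self, xm: np.ndarray) -> np.ndarray:
        """-grad U on mobile coordinates ``xm`` (nm, 3); finite everywhere."""
        s = self.spec
        dx = xm - s.site_center
        r = np.linalg.norm(dx, axis=1)
        f = np.zeros_like(xm)
        safe = np.where(r > 0, r, 1.0)
        rhat = dx / safe[:, None]
        if s.well_depth > 0:
            g = (s.well_depth / s.well_width**2) * np.exp(
                -(r**2) / (2.0 * s.well_width**2)
            )
            f -= g[:, None] * dx
        if s.excluded_radius > 0:
            pen = np.maximum(s.excluded_radius - r, 0.0)
            f += (s.core_strength * pen)[:, None] * rhat
        out = np.maximum(r - s.confinement_radius, 0.0)
        f -= (s.confinement_strength * out)[:, None] * rhat
        if self.rep_i.size and s.copy_repulsion_strength > 0:
            dv = xm[self.rep_i] - xm[self.rep_j]
            d = np.linalg.norm(dv, axis=1)
            inside = np.flatnonzero((d < s.copy_repulsion_range) & (d > 0))
            if inside.size:
                d_in = d[inside]
                mag = (
                    2.0
                    * s.copy_repulsion_strength
                    / s.copy_repulsion_range
                    * (1.0 - d_in / s.copy_repulsion_range)
                )
                fv = (mag / d_in)[:, None] * dv[inside]
                np.add.at(f, self.rep_i[inside], fv)
                np.add.at(f, self.rep_j[inside], -fv)
        if self.bond_i.size:
            dv = xm[self.bond_i] - xm[self.bond_j]
            d = np.linalg.norm(dv, axis=1)
            safe_d = np.where(d > 0, d, 1.0)
            mag = -s.bond_strength * (d - self.bond_rest) / safe_d
            fv = mag[:, None] * dv
            np.add.at(f, self.bond_i, fv)
            np.add.at(f, self.bond_j, -fv)
        return f


def toy_energy(state: SystemState, spec: ToyPotentialSpec) -> float:
    """Total potential energy of a state."""
    ff = _ForceField(spec, state.copy_id)
    return ff.energy(state.positions[ff.mobile])


def toy_force(state: SystemState, spec: ToyPotentialSpec) -> np.ndarray:
    """-grad U per particle, (n, 3); zero on frozen marker particles."""
    ff = _ForceField(spec, state.copy_id)
    f = np.zeros_like(state.positions)
    f[ff.mobile] = ff.force(state.positions[ff.mobile])
    return f


def radial_potential(r: np.ndarray | float, spec: ToyPotentialSpec) -> np.ndarray:
    """Single-particle potential as a function of distance from the site.

    Used as the analytic Boltzmann oracle for one isolated ligand:
    p(r) dr ∝ exp(-U(r)/kT) r^2 dr.
    """
    r = np.asarray(r, dtype=float)
    u = -spec.well_depth * np.exp(-(r**2) / (2.0 * spec.well_width**2))
    u = u + 0.5 * spec.core_strength * np.maximum(spec.excluded_radius - r, 0.0) ** 2
    u = u + 0.5 * spec.confinement_strength * np.maximum(
        r - spec.confinement_radius, 0.0
    ) ** 2
    return u


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB)
# ---------------------------------------------------------------------------


def run_segment(
    state: SystemState,
    spec: ToyPotentialSpec,
    params: DynamicsParams,
    seed: int | np.random.Generator,
) -> list[Snapshot]:
    """Integrate one short Langevin segment and record M snapshots.

    BAOAB splitting: B (half kick) - A (half drift) - O (Ornstein-Uhlenbeck
    velocity refresh) - A - B.  One snapshot is recorded every
    ``n_steps_per_frame`` steps, ``frames_per_segment`` times.  The input
    state is not mutated; output is bitwise-deterministic given the seed.

    Raises
    ------
    IntegrationError
        If coordinates become non-finite, reporting the step index.
    """
    ff = _ForceField(spec, state.copy_id)
    rng = _as_rng(seed)
    mob = ff.mobile
    x_full = state.positions.copy()
    xm = x_full[mob].copy()
    vm = state.velocities[mob].copy()
    m = state.masses[mob][:, None]
    dt = params.dt
    c1 = math.exp(-params.friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * params.temperature / m)
    half = 0.5 * dt
    f = ff.force(xm)
    snapshots: list[Snapshot] = []
    step = 0
    nm = mob.size
    for frame in range(params.frames_per_segment):
        for _ in range(params.n_steps_per_frame):
            vm += half * f / m
            xm += half * vm
            vm *= c1
            vm += c2 * rng.standard_normal((nm, 3))
            xm += half * vm
            f = ff.force(xm)
            vm += half * f / m
            step += 1
            if not np.isfinite(xm).all():
                raise IntegrationError(
                    f"non-finite coordinates at step {step} of segment"
                )
        pos = x_full.copy()
        pos[mob] = xm
        vel = np.zeros_like(pos)
        vel[mob] = vm
        snapshots.append(
            Snapshot(
                SystemState(pos, vel, state.masses.copy(), state.copy_id.copy()),
                frame=frame,
            )
        )
    return snapshots


def run_plain_md(
    state: SystemState,
    spec: ToyPotentialSpec,
    params: DynamicsParams,
    n_frames: int,
    seed: int | np.random.Generator,
) -> list[Snapshot]:
    """One continuous Langevin trajectory of ``n_frames`` recorded frames.

    The conventional-MD reference: no selection, no velocity regeneration.
    """
    p = dataclasses.replace(params, frames_per_segment=n_frames)
    return run_segment(state, spec, p, seed)
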