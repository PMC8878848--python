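"""Physics and efficiency validation studies on the built-in toy systems.

These are the package's own benchmark computations: statistical-mechanics
checks of the Langevin engine (Maxwell-Boltzmann velocities, equipartition
in a harmonic bowl, the radial Boltzmann distribution in the funnel), the
enrichment study comparing cascade selection against plain dynamics of equal
step budget on the hard funnel, and the free-energy recovery check on the
analytic double well.  Every study is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from .cli_io import make_fixture
from .model_system import (
    DynamicsParams,
    SystemState,
    ToyPotentialSpec,
    arrange_ligand_copies,
    draw_mb_velocities,
    radial_potential,
    run_plain_md,
    run_segment,
)
from .msm import profile_from_rc_segments
from .pacs_engine import CUTOFF, derive_seed, run_pacs
from .reaction_coordinates import evaluate_rc_pool

__all__ = [
    "mb_velocity_variance",
    "harmonic_position_variance_ratio",
    "radial_boltzmann_zscores",
    "enrichment_study",
    "double_well_recovery",
]


def mb_velocity_variance(seed: int, n: int = 100_000) -> float:
    """Per-component sample variance of n unit-mass velocity draws at kT=1."""
    v = draw_mb_velocities(np.ones(n), temperature=1.0, seed=seed)
    return float(v.var())


def harmonic_position_variance_ratio(
    seed: int,
    stiffness: float = 4.0,
    n_particles: int = 16,
    n_frames: int = 20_000,
) -> float:
    """Positional variance in a harmonic bowl, as a fraction of kT/k.

    Equipartition predicts per-axis variance kT/k; the ratio should be 1.
    Non-interacting walkers are batched as independent ligand copies.
    """
    spec = ToyPotentialSpec(
        well_depth=0.0, excluded_radius=0.0, confinement_radius=1e-9,
        confinement_strength=stiffness, copy_repulsion_strength=0.0,
    )
    rng = np.random.default_rng(seed)
    state = SystemState(
        positions=rng.normal(scale=0.5, size=(n_particles, 3)),
        velocities=np.zeros((n_particles, 3)),
        masses=np.ones(n_particles),
        copy_id=np.arange(n_particles),
    )
    params = DynamicsParams(dt=0.02, temperature=1.0, friction=1.0,
                            n_steps_per_frame=2, frames_per_segment=n_frames)
    frames = run_segment(state, spec, params, seed=seed)
    burn = n_frames // 40
    x = np.stack([s.state.positions for s in frames[burn:]])
    return float(x.var() * stiffness)


def radial_boltzmann_zscores(
    seed: int,
    n_frames: int = 520,
    n_bins: int = 12,
) -> np.ndarray:
    """Per-bin multinomial z-scores of the sampled radial distribution.

    Eight non-interacting ligand copies equilibrate in a small funnel; the
    histogram of site distances is compared against the analytic weight
    exp(-U(r)/kT) r^2 integrated over each bin.  Samples are spaced 24 time
    units apart (well beyond the radial correlation time) so the multinomial
    error model applies.
    """
    spec = ToyPotentialSpec(
        well_depth=2.5, well_width=1.0, excluded_radius=1.2,
        confinement_radius=5.0, copy_repulsion_strength=0.0,
    )
    state = arrange_ligand_copies(
        spec, n_copies=8, r_min=1.5, r_max=4.5, min_separation=0.01, seed=seed
    )
    params = DynamicsParams(dt=0.02, n_steps_per_frame=1200,
                            frames_per_segment=n_frames)
    frames = run_segment(state, spec, params, seed=seed)
    radii = np.concatenate([
        np.linalg.norm(
            s.state.positions[s.state.copy_id >= 0] - spec.site_center, axis=1
        )
        for s in frames[20:]
    ])
    edges = np.linspace(0.8, 6.0, n_bins + 1)
    weights = np.array([
        quad(lambda x: np.exp(-radial_potential(x, spec)) * x * x, a, b)[0]
        for a, b in zip(edges[:-1], edges[1:])
    ])
    p = weights / weights.sum()
    inside = radii[(radii >= edges[0]) & (radii <= edges[-1])]
    obs, _ = np.histogram(inside, bins=edges)
    n = inside.size
    return (obs - n * p) / np.sqrt(n * p * (1.0 - p))


def _pacs_trial(name_seed: int, n_copies: int) -> tuple[bool, int]:
    fx = make_fixture("funnel-hard", seed=name_seed, n_copies=n_copies)
    result = run_pacs(fx["sampling"], fx["adapter"], fx["initial"])
    config = fx["sampling"]
    success = result.termination_reason == CUTOFF
    cycles = result.n_cycles if success else config.max_cycles + 1
    return success, cycles


def _plain_trial(name_seed: int) -> bool:
    """Single continuous trajectory with the full cascade step budget."""
    fx = make_fixture("funnel-hard", seed=name_seed, n_copies=1)
    config = fx["sampling"]
    budget = config.max_cycles * config.n_replicas * config.frames_per_segment
    traj = run_plain_md(
        fx["initial"], fx["adapter"].spec, fx["adapter"].params, budget,
        seed=derive_seed(name_seed, "trial", 1),
    )
    rc = evaluate_rc_pool(traj, config.rc)
    return bool(rc.min() < config.cutoff)


def enrichment_study(seed: int, n_trials: int = 20) -> dict:
    """Cascade selection vs. plain dynamics on the hard funnel.

    For each of ``n_trials`` seeds: a 6-copy cascade run, a 1-copy cascade
    run, and a plain Langevin trajectory of identical total step budget in
    the dilute (single-copy) environment.  Returns success fractions and
    cycles-to-cutoff (budget + 1 for censored runs).
    """
    pacs_success, cycles_multi, cycles_single, plain_success = [], [], [], []
    for t in range(n_trials):
        trial_seed = derive_seed(seed, "trial", t)
        ok6, c6 = _pacs_trial(trial_seed, n_copies=6)
        _, c1 = _pacs_trial(trial_seed, n_copies=1)
        pacs_success.append(ok6)
        cycles_multi.append(c6)
        cycles_single.append(c1)
        plain_success.append(_plain_trial(trial_seed))
    return {
        "n_trials": n_trials,
        "pacs_success_fraction": float(np.mean(pacs_success)),
        "plain_success_fraction": float(np.mean(plain_success)),
        "median_cycles_multi_copy": float(np.median(cycles_multi)),
        "median_cycles_single_copy": float(np.median(cycles_single)),
        "cycles_multi_copy": cycles_multi,
        "cycles_single_copy": cycles_single,
    }


def double_well_recovery(
    seed: int, n_segments: int = 20, n_frames: int = 4000, k: int = 30
) -> dict:
    """Recover the analytic basin free-energy gap of the 1-D double well.

    Long unbiased Langevin segments are fed to the full MSM pipeline; the
    basin gap is the log-ratio of stationary probability left/right of the
    barrier top, compared against the quadrature of the Boltzmann weight.
    """
    fx = make_fixture("double-well-1d", seed=seed)
    segments = fx["sample"](n_segments, n_frames)
    model, table = profile_from_rc_segments(
        segments, k=k, lag_grid=(1, 2, 5, 10), kBT=fx["kBT"], seed=seed
    )
    left = model.centers[:, 0] < fx["split"]
    est = float(-np.log(model.pi[~left].sum() / model.pi[left].sum()))
    return {
        "delta_f_true": float(fx["delta_F"]),
        "delta_f_estimate": est,
        "error": abs(est - fx["delta_F"]),
        "model": model,
        "table": table,
    }
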