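"""Toy substrate: forces, arrangement, velocity draws, Langevin segments."""

import dataclasses

import numpy as np
import pytest

from pacsmd import (
    DynamicsParams,
    IntegrationError,
    PackingError,
    SystemState,
    ToyPotentialSpec,
    arrange_ligand_copies,
    draw_mb_velocities,
    run_segment,
    toy_energy,
    toy_force,
)
from pacsmd.model_system import SITE_COPY_ID


def _numerical_gradient(state, spec, h=1e-5):
    grad = np.zeros_like(state.positions)
    for i in range(state.n_particles):
        if state.copy_id[i] < 0:
            continue
        for d in range(3):
            plus = state.copy()
            plus.positions[i, d] += h
            minus = state.copy()
            minus.positions[i, d] -= h
            grad[i, d] = (toy_energy(plus, spec) - toy_energy(minus, spec)) / (2 * h)
    return grad


class TestForces:
    def test_zero_at_site_center_by_symmetry(self, funnel_spec):
        state = SystemState(
            positions=[funnel_spec.site_center],
            velocities=np.zeros((1, 3)),
            masses=[1.0],
            copy_id=[0],
        )
        assert np.allclose(toy_force(state, funnel_spec), 0.0)

    def test_pair_force_vanishes_beyond_repulsion_range(self):
        spec = ToyPotentialSpec(
            well_depth=0.0, excluded_radius=0.0, confinement_radius=100.0,
            copy_repulsion_strength=5.0, copy_repulsion_range=2.0,
        )
        state = SystemState(
            positions=[[0, 0, 0], [5, 0, 0]],
            velocities=np.zeros((2, 3)),
            masses=[1.0, 1.0],
            copy_id=[0, 1],
        )
        assert np.allclose(toy_force(state, spec), 0.0)

    @pytest.mark.parametrize("n_copies,ligand_sites", [(1, 1), (6, 1), (2, 6)])
    def test_matches_central_difference_gradient(self, n_copies, ligand_sites):
        spec = ToyPotentialSpec(
            confinement_radius=8.0,
            copy_repulsion_range=4.0,
            ligand_sites=ligand_sites,
        )
        state = arrange_ligand_copies(
            spec, n_copies=n_copies, r_min=2.0, r_max=7.0, min_separation=1.0, seed=3
        )
        # push one copy outside the confinement wall to exercise that term
        state.positions[-1] *= 1.6
        f = toy_force(state, spec)
        fd = -_numerical_gradient(state, spec)
        assert np.allclose(f, fd, rtol=1e-6, atol=1e-6)

    def test_force_is_finite_even_at_overlap(self, funnel_spec):
        state = SystemState(
            positions=np.zeros((2, 3)), velocities=np.zeros((2, 3)),
            masses=[1.0, 1.0], copy_id=[0, 1],
        )
        assert np.isfinite(toy_force(state, funnel_spec)).all()


class TestArrangement:
    def test_single_copy_lands_in_shell(self, funnel_spec):
        st = arrange_ligand_copies(
            funnel_spec, n_copies=1, r_min=5.0, r_max=10.0, min_separation=3.0, seed=0
        )
        r = np.linalg.norm(st.positions[st.copy_id == 0] - funnel_spec.site_center)
        assert 5.0 <= r <= 10.0
        assert (st.copy_id == SITE_COPY_ID).sum() == 1

    def test_six_copies_respect_min_separation(self, six_copy_state):
        pos = six_copy_state.positions[six_copy_state.copy_id >= 0]
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.shape == (6, 6) and d.min() >= 2.5

    def test_infeasible_packing_raises(self, funnel_spec):
        with pytest.raises(PackingError, match="min_separation"):
            arrange_ligand_copies(
                funnel_spec, n_copies=50, r_min=5.0, r_max=5.2,
                min_separation=6.0, seed=0, max_tries=200,
            )

    def test_shell_outside_walls_rejected(self, funnel_spec):
        with pytest.raises(ValueError, match="excluded_radius"):
            arrange_ligand_copies(
                funnel_spec, n_copies=1, r_min=0.5, r_max=10.0,
                min_separation=1.0, seed=0,
            )

    def test_deterministic_given_seed(self, funnel_spec):
        a = arrange_ligand_copies(funnel_spec, 4, 5.0, 10.0, 2.0, seed=9)
        b = arrange_ligand_copies(funnel_spec, 4, 5.0, 10.0, 2.0, seed=9)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)


class TestVelocities:
    def test_zero_temperature_gives_zero_velocities(self):
        v = draw_mb_velocities(np.ones(10), temperature=0.0, seed=1)
        assert np.all(v == 0.0)

    def test_component_variance_matches_temperature(self):
        n = 100_000
        v = draw_mb_velocities(np.full(n, 2.0), temperature=1.5, seed=5)
        expected = 1.5 / 2.0
        se = expected * np.sqrt(2.0 / (3 * n - 1))
        assert abs(v.var() - expected) < 3 * se

    def test_seed_contract(self):
        m = np.ones(5)
        assert np.array_equal(
            draw_mb_velocities(m, 1.0, seed=3), draw_mb_velocities(m, 1.0, seed=3)
        )
        assert not np.array_equal(
            draw_mb_velocities(m, 1.0, seed=3), draw_mb_velocities(m, 1.0, seed=4)
        )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            draw_mb_velocities(np.array([1.0, 0.0]), 1.0, seed=0)


class TestSegments:
    def test_zero_temperature_rest_state_is_fixed_point(self):
        spec = ToyPotentialSpec(well_depth=5.0, excluded_radius=0.0,
                                confinement_radius=10.0)
        state = SystemState([[0.0, 0.0, 0.0]], np.zeros((1, 3)), [1.0], [0])
        params = DynamicsParams(temperature=0.0, frames_per_segment=4)
        frames = run_segment(state, spec, params, seed=0)
        for s in frames:
            assert np.array_equal(s.state.positions, state.positions)

    def test_frame_bookkeeping(self, funnel_spec, six_copy_state):
        params = DynamicsParams(frames_per_segment=7, n_steps_per_frame=3)
        frames = run_segment(six_copy_state, funnel_spec, params, seed=2)
        assert [s.frame for s in frames] == list(range(7))

    def test_bitwise_determinism_and_no_mutation(self, funnel_spec, six_copy_state):
        before = six_copy_state.positions.copy()
        params = DynamicsParams(frames_per_segment=3)
        a = run_segment(six_copy_state, funnel_spec, params, seed=11)
        b = run_segment(six_copy_state, funnel_spec, params, seed=11)
        assert np.array_equal(six_copy_state.positions, before)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.state.positions, sb.state.positions)
            assert np.array_equal(sa.state.velocities, sb.state.velocities)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_blow_up_reports_step_index(self, funnel_spec, six_copy_state):
        params = DynamicsParams(dt=50.0, frames_per_segment=5)
        with pytest.raises(IntegrationError, match="step"):
            run_segment(six_copy_state, funnel_spec, params, seed=0)

    def test_kinetic_energy_equipartition(self):
        # one particle in a harmonic bowl: <KE>/dof = kT/2 within 5%
        spec = ToyPotentialSpec(well_depth=0.0, excluded_radius=0.0,
                                confinement_radius=1e-9, confinement_strength=4.0)
        state = SystemState([[0.3, 0.0, 0.0]], np.zeros((1, 3)), [1.0], [0])
        params = DynamicsParams(dt=0.02, temperature=1.0, friction=1.0,
                                n_steps_per_frame=5, frames_per_segment=20000)
        frames = run_segment(state, spec, params, seed=21)
        ke = np.array([0.5 * (s.state.velocities ** 2).sum() for s in frames[500:]])
        assert abs(ke.mean() / 3.0 - 0.5) < 0.05 * 0.5
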