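"""Markov-model estimation: counting, detailed balance, timescales, profiles."""

import itertools

import numpy as np
import pytest

from pacsmd import (
    DiscreteTrajectorySet,
    profile_along_rc,
    run_pacs,
    cluster_microstates,
    count_transitions,
    estimate_T,
    free_energy_profile,
    implied_timescales,
    make_fixture,
    profile_from_rc_segments,
    select_lag,
    stationary_distribution,
)


def _dtrajs(segments, n_states=None):
    segs = [np.asarray(s, dtype=int) for s in segments]
    n = n_states or (max(int(s.max()) for s in segs if s.size) + 1)
    return DiscreteTrajectorySet(segs, n_states=n, centers=np.arange(n, dtype=float))


def _enumerate_counts(segments, n, lag):
    """Independent oracle: exhaustively enumerate lagged pairs."""
    c = np.zeros((n, n))
    for s in segments:
        for t in range(len(s) - lag):
            c[s[t], s[t + lag]] += 1
    return c


class TestClustering:
    def test_k1_center_is_mean(self, rng):
        x = rng.normal(size=50)
        dt = cluster_microstates([x], k=1, seed=0)
        assert np.all(dt.segments[0] == 0)
        assert dt.centers[0, 0] == pytest.approx(x.mean())

    def test_separated_blobs_split_perfectly(self, rng):
        lo = rng.normal(0.0, 0.1, size=100)
        hi = rng.normal(10.0, 0.1, size=100)
        dt = cluster_microstates([np.concatenate([lo, hi])], k=2, seed=0)
        labels = dt.segments[0]
        assert np.all(labels[:100] == 0) and np.all(labels[100:] == 1)

    def test_every_frame_assigned_to_nearest_center(self, rng):
        x = rng.normal(size=(200, 2))
        dt = cluster_microstates([x], k=5, seed=1)
        d = np.linalg.norm(x[:, None, :] - dt.centers[None], axis=-1)
        assert np.array_equal(dt.segments[0], d.argmin(axis=1))

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            cluster_microstates([np.array([1.0, 1.0, 2.0])], k=3, seed=0)


class TestCounting:
    def test_hand_enumerated_short_trajectory(self):
        dt = _dtrajs([[0, 0, 1, 1]])
        assert np.array_equal(count_transitions(dt, 1), [[1, 1], [0, 1]])

    def test_lag_beyond_segment_length_gives_zero(self):
        dt = _dtrajs([[0, 1, 0]], n_states=2)
        assert count_transitions(dt, 5).sum() == 0

    def test_total_counts_window_arithmetic(self, rng):
        segs = [rng.integers(0, 4, size=n) for n in (3, 9, 17)]
        dt = _dtrajs(segs, n_states=4)
        for lag in (1, 2, 5):
            expected = sum(max(0, len(s) - lag) for s in segs)
            assert count_transitions(dt, lag).sum() == expected

    def test_matches_exhaustive_enumeration(self, rng):
        segs = [rng.integers(0, 5, size=30) for _ in range(4)]
        dt = _dtrajs(segs, n_states=5)
        for lag in (1, 3):
            assert np.array_equal(
                count_transitions(dt, lag), _enumerate_counts(segs, 5, lag)
            )

    def test_no_cross_segment_pairs(self):
        split = _dtrajs([[0, 1], [1, 0]], n_states=2)
        joined = _dtrajs([[0, 1, 1, 0]], n_states=2)
        assert count_transitions(split, 1).sum() == 2
        assert count_transitions(joined, 1).sum() == 3


class TestEstimator:
    def test_row_normalization(self):
        T = estimate_T(np.array([[1.0, 1.0], [0.0, 1.0]]), reversible=False)
        assert np.allclose(T, [[0.5, 0.5], [0.0, 1.0]])

    def test_symmetric_counts_make_both_estimators_agree(self):
        c = np.array([[4.0, 2.0], [2.0, 6.0]])
        assert np.allclose(estimate_T(c, True), estimate_T(c, False))

    def test_reversible_estimator_satisfies_detailed_balance(self):
        c = np.array([[8.0, 2.0], [1.0, 9.0]])
        T = estimate_T(c, reversible=True)
        pi = stationary_distribution(T)
        assert np.max(np.abs(pi[:, None] * T - (pi[:, None] * T).T)) < 1e-12

    def test_disconnected_states_trimmed(self):
        c = np.zeros((3, 3))
        c[0, 1] = c[1, 0] = 5.0  # state 2 never visited
        T = estimate_T(c, reversible=True)
        assert T.shape == (2, 2)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            estimate_T(np.zeros((2, 2)))


class TestTimescales:
    def test_symmetric_two_state_closed_form(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        ts = implied_timescales(T, lag=1)
        assert ts[0] == pytest.approx(-1.0 / np.log(0.8), abs=1e-12)

    def test_eigenvalue_exp_minus_one_gives_unit_timescale(self):
        lam = np.exp(-1.0)
        T = np.array([[(1 + lam) / 2, (1 - lam) / 2], [(1 - lam) / 2, (1 + lam) / 2]])
        assert implied_timescales(T, 1)[0] == pytest.approx(1.0)

    def test_identity_matrix_has_no_finite_timescale(self):
        ts = implied_timescales(np.eye(3), lag=1)
        assert np.all(np.isinf(ts))

    def test_lag_scaling(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert implied_timescales(T, 5)[0] == pytest.approx(
            5 * implied_timescales(T, 1)[0]
        )


class TestLagSelection:
    def test_markovian_chain_selects_smallest_lag(self):
        fx = make_fixture("markov-2state", seed=3, p01=0.1, p10=0.1)
        segs = fx["sample"](10, 1000)
        dt = _dtrajs(segs, n_states=2)
        assert select_lag(dt, [1, 2, 5], plateau_tol=0.2) == 1

    def test_infinite_tolerance_returns_first_lag(self):
        dt = _dtrajs([[0, 0, 0, 0, 1, 1, 1, 1] * 4], n_states=2)
        assert select_lag(dt, [1, 2, 4], plateau_tol=np.inf) == 1

    def test_singleton_grid(self):
        dt = _dtrajs([[0] * 6 + [1] * 6], n_states=2)
        assert select_lag(dt, [2]) == 2

    def test_grid_must_increase(self):
        dt = _dtrajs([[0, 1, 0]], n_states=2)
        with pytest.raises(ValueError, match="increasing"):
            select_lag(dt, [2, 2])


class TestStationary:
    def test_symmetric_chain_is_uniform(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert np.allclose(stationary_distribution(T), [0.5, 0.5])

    def test_birth_death_closed_form(self):
        T = np.array([[0.8, 0.2], [0.1, 0.9]])
        assert np.allclose(stationary_distribution(T), [1 / 3, 2 / 3])

    def test_fixed_point_residual_on_random_reversible(self, rng):
        for _ in range(10):
            c = rng.integers(1, 50, size=(4, 4)).astype(float)
            T = estimate_T(c, reversible=True)
            pi = stationary_distribution(T)
            assert np.max(np.abs(pi @ T - pi)) <= 1e-10

    def test_reducible_matrix_names_blocks(self):
        T = np.eye(2)
        with pytest.raises(ValueError, match="blocks"):
            stationary_distribution(T)


class TestFreeEnergy:
    def test_uniform_distribution_is_flat_zero(self):
        assert np.allclose(free_energy_profile(np.full(4, 0.25)), 0.0)

    def test_four_to_one_population_ratio(self):
        f = free_energy_profile(np.array([0.8, 0.2]), kBT=1.0)
        assert f[0] == 0.0
        assert f[1] == pytest.approx(np.log(4.0))

    def test_minimum_pinned_to_zero(self, rng):
        pi = rng.dirichlet(np.ones(6))
        f = free_energy_profile(pi)
        assert f.min() == 0.0
        assert np.argmin(f) == np.argmax(pi)


class TestConsistencyLimit:
    def test_estimate_improves_as_data_quadruples(self):
        fx = make_fixture("markov-2state", seed=11, p01=0.15, p10=0.05)
        errs = []
        for n_frames in (500, 2000):
            segs = fx["sample"](8, n_frames)
            dt = _dtrajs(segs, n_states=2)
            T = estimate_T(count_transitions(dt, 1), reversible=False)
            errs.append(np.abs(T - fx["T"]).max())
        assert errs[1] < errs[0]
        assert errs[1] < 0.02


class TestProfiles:
    def test_constant_trajectory_single_state_zero_f(self):
        model, table = profile_from_rc_segments([np.full(20, 3.5)], k=30)
        assert model.pi.tolist() == [1.0]
        assert table["free_energy"].tolist() == [0.0]

    def test_table_sorted_by_center(self, rng):
        segs = [rng.normal(size=300) for _ in range(4)]
        _, table = profile_from_rc_segments(segs, k=8, lag_grid=(1, 2), seed=0)
        centers = table["rc_center"].to_numpy()
        assert np.all(np.diff(centers) > 0)

    def test_profile_along_binding_coordinate_of_a_run(self):
        fx = make_fixture("funnel-easy", seed=2)
        result = run_pacs(fx["sampling"], fx["adapter"], fx["initial"])
        assert result.n_cycles >= 2
        model, table = profile_along_rc(result, k=6, lag_grid=(1, 2), seed=0)
        assert np.all(np.diff(table["rc_center"]) > 0)
        assert table["free_energy"].min() == 0.0
        assert np.allclose(model.T.sum(axis=1), 1.0, atol=1e-10)

    def test_profile_requires_two_cycles(self):
        fx = make_fixture("funnel-easy", seed=2)
        import dataclasses

        config = dataclasses.replace(fx["sampling"], cutoff=50.0)
        result = run_pacs(config, fx["adapter"], fx["initial"])
        with pytest.raises(ValueError, match="2 cycles"):
            profile_along_rc(result)

    def test_model_invariants_on_sampled_data(self, rng):
        segs = [rng.normal(size=400) for _ in range(4)]
        model, _ = profile_from_rc_segments(segs, k=6, lag_grid=(1, 2), seed=0)
        assert np.allclose(model.T.sum(axis=1), 1.0, atol=1e-10)
        assert model.pi.sum() == pytest.approx(1.0, abs=1e-10)
        flux = model.pi[:, None] * model.T
        assert np.max(np.abs(flux - flux.T)) < 1e-8
        assert model.free_energy.min() == 0.0
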