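import numpy as np
import pytest
from scipy.optimize import minimize

import informrc as rc
from informrc.arm import (AMPLITUDES, DIRECTIONS, FREQUENCIES, ArmModel,
                          NoiseOpts, TrialCondition, endpoint_trajectory,
                          forward_kinematics, generate_natural_transitions,
                          generate_trial, inverse_dynamics, inverse_kinematics,
                          make_conditions, minimum_jerk, muscle_kinematics,
                          select_muscles, static_optimisation)


class TestConditions:
    def test_factorial_has_20_unique_cells(self):
        conds = make_conditions()
        assert len(conds) == 20
        assert len({(c.direction, c.amplitude, c.frequency) for c in conds}) == 20

    def test_each_direction_in_four_cells(self):
        conds = make_conditions()
        for d in DIRECTIONS:
            assert sum(c.direction == d for c in conds) == 4

    def test_frequencies_are_metronome_paced(self):
        assert {c.frequency for c in make_conditions()} == {1.0, 0.75}

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            TrialCondition("F", 0.25, 1.0)


class TestEndpointTrajectory:
    def test_cycle_boundaries_at_origin_and_peak_at_amplitude(self):
        cond = TrialCondition("C", 0.4, 1.0, n_cycles=3)
        g = endpoint_trajectory(cond, fs=120.0)
        P = 120
        d = np.hypot(g[0], g[1])
        for k in range(3):
            assert d[k * P] == pytest.approx(0.0, abs=1e-12)
            assert d[k * P + P // 2] == pytest.approx(0.4, abs=1e-12)

    def test_minimum_jerk_quarter_point_value(self):
        # s at a quarter of the outward half-period is 0.103515625 * A
        assert minimum_jerk(0.25) == pytest.approx(0.103515625, abs=1e-15)
        cond = TrialCondition("C", 0.25, 1.0, n_cycles=1)
        g = endpoint_trajectory(cond, fs=120.0)
        assert g[1, 15] == pytest.approx(0.103515625 * 0.25, abs=1e-12)

    def test_direction_geometry(self):
        gE = endpoint_trajectory(TrialCondition("E", 0.25, 1.0, 1), 120.0)
        assert gE[0, 60] == pytest.approx(0.25, abs=1e-12)   # +90 deg -> +x
        assert gE[1, 60] == pytest.approx(0.0, abs=1e-12)

    def test_zero_velocity_at_taps(self):
        g = endpoint_trajectory(TrialCondition("D", 0.4, 0.75, 2), 120.0)
        v = np.gradient(np.hypot(g[0], g[1]), 1 / 120.0)
        P = 160
        assert abs(v[P]) < 1e-2 and abs(v[P + P // 2]) < 1e-2


class TestKinematics:
    def test_ik_fk_round_trip(self, arm):
        rng = np.random.default_rng(0)
        r = rng.uniform(abs(arm.L1 - arm.L2) + 0.02, arm.L1 + arm.L2 - 0.02, 100)
        ang = rng.uniform(0, 2 * np.pi, 100)
        pts = np.vstack([r * np.cos(ang), r * np.sin(ang)])
        theta = inverse_kinematics(pts, arm)
        back = forward_kinematics(theta, arm)
        assert np.max(np.abs(back - pts)) < 1e-9

    def test_full_extension_zero_elbow(self, arm):
        p = np.array([0.0, arm.L1 + arm.L2])
        theta = inverse_kinematics(p, arm)
        assert theta[1] == pytest.approx(0.0, abs=1e-6)

    def test_equal_links_right_elbow(self):
        arm = ArmModel(L1=0.4, L2=0.4, center_offset=(0.0, 0.25))
        p = np.array([0.0, 0.4 * np.sqrt(2)])
        theta = inverse_kinematics(p, arm)
        assert abs(np.rad2deg(theta[1])) == pytest.approx(90.0, abs=1e-9)

    def test_unreachable_point_rejected(self, arm):
        with pytest.raises(ValueError):
            inverse_kinematics(np.array([0.0, arm.L1 + arm.L2 + 0.01]), arm)


class TestInverseDynamics:
    def test_static_posture_no_torque(self, arm):
        th = np.full((2, 10), 0.5)
        z = np.zeros((2, 10))
        tau = inverse_dynamics(th, z, z, arm)
        np.testing.assert_allclose(tau, 0, atol=1e-15)

    def test_single_link_limit(self):
        arm = ArmModel(L2=0.45, m2=1e-12, I2=1e-12, c2=1e-12)
        th = np.zeros((2, 5))
        dth = np.zeros((2, 5))
        ddth = np.vstack([np.full(5, 2.0), np.zeros(5)])
        tau = inverse_dynamics(th, dth, ddth, arm)
        I_total = arm.I1 + arm.m1 * arm.c1 ** 2
        np.testing.assert_allclose(tau[0], I_total * 2.0, rtol=1e-9)

    def test_energy_consistency_over_cycle(self, arm):
        cond = TrialCondition("C", 0.25, 1.0, n_cycles=4)
        g = endpoint_trajectory(cond, 120.0)
        theta = inverse_kinematics(g[:2] + np.array(arm.center_offset)[:, None],
                                   arm)
        dt = 1 / 120.0
        dth = np.gradient(theta, dt, axis=1)
        ddth = np.gradient(dth, dt, axis=1)
        tau = inverse_dynamics(theta, dth, ddth, arm)
        # net work over the interior cycles of a periodic conservative motion
        work = np.sum(tau[:, 120:360] * dth[:, 120:360]) * dt
        peak_power = np.max(np.abs(np.sum(tau * dth, axis=0)))
        assert abs(work) < 0.02 * peak_power

    def test_nonfinite_rejected(self, arm):
        bad = np.full((2, 3), np.nan)
        with pytest.raises(ValueError):
            inverse_dynamics(bad, bad, bad, arm)


class TestMuscleKinematics:
    def test_rest_length_at_zero_angles(self, arm):
        l, v = muscle_kinematics(np.zeros((2, 4)), np.zeros((2, 4)), arm)
        np.testing.assert_allclose(
            l, np.tile(arm.rest_lengths[:, None], (1, 4)), atol=1e-15)
        np.testing.assert_allclose(v, 0, atol=1e-15)

    def test_linear_length_change(self, arm):
        theta = np.array([[0.5], [0.0]])
        l, _ = muscle_kinematics(theta, np.zeros((2, 1)), arm)
        expected = arm.rest_lengths - arm.moment_arms[:, 0] * 0.5
        np.testing.assert_allclose(l[:, 0], expected, atol=1e-15)


class TestStaticOptimisation:
    def test_zero_torque_zero_activation(self, arm):
        a = static_optimisation(np.zeros(2), arm)
        np.testing.assert_allclose(a, 0, atol=1e-12)

    def test_agonist_antagonist_hand_solution(self):
        arm = ArmModel(moment_arms=np.array([[0.03, 0.0], [-0.03, 0.0],
                                             [0.0, 0.025], [0.0, -0.025]]),
                       max_forces=np.array([400.0, 400.0, 300.0, 300.0]),
                       rest_lengths=np.full(4, 0.3))
        tau1 = 3.0
        a = static_optimisation(np.array([tau1, 0.0]), arm)
        assert a[0] == pytest.approx(tau1 / (0.03 * 400.0), abs=1e-10)
        assert a[1] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(a[2:], 0, atol=1e-12)

    def test_permutation_equivariance(self, arm):
        tau = np.array([2.0, -1.5])
        a = static_optimisation(tau, arm)
        perm = np.array([3, 1, 4, 0, 2, 9, 5, 8, 7, 6])
        arm2 = ArmModel(moment_arms=arm.moment_arms[perm],
                        max_forces=arm.max_forces[perm],
                        rest_lengths=arm.rest_lengths[perm])
        a2 = static_optimisation(tau, arm2)
        np.testing.assert_allclose(a2, a[perm], atol=1e-9)

    def test_matches_slsqp_oracle(self, arm):
        """Active-set solution equals a generic constrained optimiser's."""
        B = arm.torque_matrix
        rng = np.random.default_rng(3)
        for _ in range(10):
            tau = rng.uniform(-4, 4, size=2)
            a = static_optimisation(tau, arm)
            res = minimize(lambda x: np.sum(x ** 2), np.full(arm.n_muscles, 0.1),
                           jac=lambda x: 2 * x,
                           constraints=[{"type": "eq",
                                         "fun": lambda x: B @ x - tau,
                                         "jac": lambda x: B}],
                           bounds=[(0, 1)] * arm.n_muscles, method="SLSQP",
                           options={"ftol": 1e-14, "maxiter": 300})
            assert res.success
            np.testing.assert_allclose(a, res.x, atol=5e-6)
            assert np.max(np.abs(B @ a - tau)) <= 1e-8

    def test_redundant_solution_uses_multiple_muscles(self, arm):
        a = static_optimisation(np.array([3.0, 2.0]), arm)
        assert np.sum(a > 1e-6) > 2  # min-norm spreads load over the set

    def test_infeasible_torque_reported(self, arm):
        with pytest.raises(ValueError, match="infeasible"):
            static_optimisation(np.array([1e4, 0.0]), arm)


class TestSelectMuscles:
    def test_identity_when_exactly_eight(self):
        act = np.random.default_rng(0).uniform(size=(8, 50))
        np.testing.assert_array_equal(select_muscles(act), np.arange(8))

    def test_silent_muscle_excluded(self):
        rng = np.random.default_rng(1)
        act = rng.uniform(size=(9, 50))
        act[4] = 0.2  # constant = zero range
        sel = select_muscles(act)
        assert 4 not in sel

    def test_ordering_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        act = rng.uniform(size=(12, 30))
        ranges = act.max(1) - act.min(1)
        oracle = np.sort(np.argsort(-ranges, kind="stable")[:8])
        np.testing.assert_array_equal(select_muscles(act), oracle)

    def test_too_few_muscles_rejected(self):
        with pytest.raises(ValueError):
            select_muscles(np.zeros((5, 10)))


class TestGenerateTrial:
    def test_deterministic_given_seed(self):
        c = TrialCondition("B", 0.25, 1.0, n_cycles=2)
        b1 = generate_trial(c, seed=9)
        b2 = generate_trial(c, seed=9)
        np.testing.assert_array_equal(b1.stacked(), b2.stacked())

    def test_sample_count_and_cycles(self):
        c = TrialCondition("C", 0.25, 1.0, n_cycles=10)
        b = generate_trial(c, seed=0, noise=NoiseOpts(sigma_endpoint=0.0))
        assert b.n_samples == 1200 and b.n_cycles == 10

    def test_activations_within_bounds(self):
        c = TrialCondition("E", 0.4, 0.75, n_cycles=3)
        b = generate_trial(c, seed=1)
        assert b.efference.min() >= 0.0 and b.efference.max() <= 1.0

    def test_velocity_is_derivative_of_length(self):
        c = TrialCondition("A", 0.4, 1.0, n_cycles=2)
        b = generate_trial(c, seed=2)
        M = b.efference.shape[0]
        lengths, velocities = b.afference[:M], b.afference[M:]
        deriv = np.gradient(lengths, 1 / b.fs, axis=1)
        assert np.max(np.abs(velocities - deriv)) < 1e-6


class TestNaturalTransitions:
    @pytest.fixture(scope="class")
    def trials(self):
        return generate_natural_transitions(seed=4)

    def test_four_trials_factorial(self, trials):
        metas = {(b.meta["n_taps"], b.meta["frequency"]) for b in trials}
        assert metas == {(1, 1.0), (1, 0.75), (3, 1.0), (3, 0.75)}

    def test_all_ten_targets_visited(self, trials):
        for b in trials:
            assert len(set(map(tuple, b.meta["order"]))) == 10

    def test_three_tap_trials_repeat_each_target(self, trials):
        for b in trials:
            expected = 10 * b.meta["n_taps"]
            assert b.n_cycles == expected

    def test_segment_concatenation_continuous(self):
        for b in generate_natural_transitions(seed=5,
                                              noise=NoiseOpts(sigma_endpoint=0)):
            jumps = np.abs(np.diff(b.goal[:2], axis=1))
            assert np.max(jumps) < 0.05  # bounded by one sample of motion


class TestDataset:
    def test_channel_counts(self, dataset):
        b = next(iter(dataset.trials.values()))
        assert b.goal.shape[0] == 3
        assert b.efference.shape[0] == 8
        assert b.afference.shape[0] == 16

    def test_selection_stable_without_noise(self):
        d1 = rc.generate_dataset(seed=1, noise=NoiseOpts(sigma_endpoint=0))
        d2 = rc.generate_dataset(seed=2, noise=NoiseOpts(sigma_endpoint=0))
        np.testing.assert_array_equal(d1.selection, d2.selection)

    def test_workspace_validation_rejects_short_arm(self):
        with pytest.raises(ValueError, match="outside reachable"):
            ArmModel(L1=0.2, L2=0.25)

    def test_actuation_feasibility_enforced(self):
        bad = _default = ArmModel().moment_arms.copy()
        bad[bad[:, 0] < 0, 0] *= -1  # no shoulder extensor left
        with pytest.raises(ValueError, match="agonist/antagonist"):
            ArmModel(moment_arms=bad)

    def test_csv_round_trip(self, dataset, tmp_path):
        b = dataset.trials["C1@1Hz"].slice(0, 50)
        b.to_csv(tmp_path / "trial.csv")
        back = rc.SignalBundle.from_csv(tmp_path / "trial.csv")
        np.testing.assert_allclose(back.stacked(), b.stacked(), atol=1e-9)
        assert back.fs == b.fs
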