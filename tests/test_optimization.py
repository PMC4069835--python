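"""Min-max static optimization: bounds, LP solve, oracles, postprocessing."""

import numpy as np
import pytest

from propriosim.muscle import MuscleParams
from propriosim.optimization import (LpProblem, activation_bounds,
                                     bootstrap_state, build_lp,
                                     postprocess_branch_sharing,
                                     solve_min_max, step_state)
from propriosim.validation import grid_resolution_bound, grid_search_objective


class TestActivationBounds:
    def test_zero_activation_floor(self):
        a_min, _ = activation_bounds(0.0, 0.05)
        assert a_min == 0.0

    def test_full_activation_ceiling(self):
        _, a_max = activation_bounds(1.0, 0.05)
        assert a_max == 1.0

    def test_worked_values_at_120hz(self):
        a_min, a_max = activation_bounds(0.5, 1.0 / 120.0)
        assert a_min == pytest.approx(0.39583, abs=1e-5)
        assert a_max == pytest.approx(0.72222, abs=1e-5)

    def test_bracket_previous_activation(self, rng):
        a = rng.uniform(0, 1, 50)
        a_min, a_max = activation_bounds(a, 1.0 / 120.0)
        assert np.all(a_min <= a + 1e-12)
        assert np.all(a_max >= a - 1e-12)
        assert np.all((a_min >= 0) & (a_max <= 1))

    def test_dt_to_zero_collapses_bounds(self):
        a_min, a_max = activation_bounds(0.37, 1e-9)
        assert a_max - a_min == pytest.approx(0.0, abs=1e-6)


class TestBuildSolve:
    def test_single_muscle_closed_form(self):
        # torque 10 with gain 25 -> a = 0.4 uniquely
        p = build_lp(np.array([[25.0]]), np.zeros(1), np.array([10.0]),
                     np.zeros(1), np.ones(1))
        res = solve_min_max(p)
        assert res.status == "optimal"
        assert res.activations[0] == pytest.approx(0.4, abs=1e-8)
        assert res.beta == pytest.approx(0.4, abs=1e-8)

    def test_zero_net_torque_all_zero(self):
        gains = np.array([[25.0], [18.0]])
        passive = np.array([3.0])
        p = build_lp(gains, passive, passive.copy(), np.zeros(2), np.ones(2))
        res = solve_min_max(p)
        assert res.status == "optimal"
        assert np.allclose(res.activations, 0.0, atol=1e-9)

    def test_matrix_shapes(self):
        p = LpProblem(np.ones((17, 4)), np.zeros(4), np.zeros(17), np.ones(17))
        c, a_ub, b_ub, a_eq, b_eq, bounds = p.matrices()
        assert c.shape == (18,)
        assert a_ub.shape == (17, 18)
        assert a_eq.shape == (4, 18)
        assert len(bounds) == 18

    def test_identical_muscles_split_equally(self):
        p = LpProblem(np.array([[25.0], [25.0]]), np.array([10.0]),
                      np.zeros(2), np.ones(2))
        res = solve_min_max(p)
        assert res.status == "optimal"
        assert np.allclose(res.activations, [0.2, 0.2], atol=1e-8)
        assert res.beta == pytest.approx(0.2, abs=1e-8)

    def test_capacity_exceeded_relaxes(self):
        p = LpProblem(np.array([[25.0], [25.0]]), np.array([80.0]),
                      np.zeros(2), np.ones(2))
        res = solve_min_max(p)
        assert res.status == "relaxed"
        assert np.allclose(res.activations, 1.0, atol=1e-8)
        assert res.torque_residual[0] == pytest.approx(-30.0, abs=1e-6)

    def test_degenerate_joint_goes_relaxed(self):
        gains = np.array([[25.0, 0.0]])
        p = LpProblem(gains, np.array([5.0, 2.0]), np.zeros(1), np.ones(1))
        res = solve_min_max(p)
        assert res.status == "relaxed"
        assert res.torque_residual[1] == pytest.approx(-2.0, abs=1e-8)

    def test_beta_equals_max_activation(self, rng):
        for _ in range(10):
            m = int(rng.integers(2, 6))
            gains = rng.uniform(5, 40, (m, 2))
            a_true = rng.uniform(0.05, 0.5, m)
            p = LpProblem(gains, gains.T @ a_true, np.zeros(m), np.ones(m))
            res = solve_min_max(p)
            assert res.status == "optimal"
            assert res.beta == pytest.approx(res.activations.max(), abs=1e-7)

    def test_torque_monotone_in_scaling(self, rng):
        gains = rng.uniform(5, 40, (4, 2))
        target = gains.T @ rng.uniform(0.1, 0.5, 4)
        betas = []
        for k in (1.0, 0.7, 0.4, 0.1):
            p = LpProblem(gains, k * target, np.zeros(4), np.ones(4))
            betas.append(solve_min_max(p).beta)
        assert np.all(np.diff(betas) <= 1e-9)

    def test_recovery_beta_bounded_by_generator(self, rng):
        for _ in range(10):
            m = int(rng.integers(2, 8))
            gains = rng.uniform(5, 40, (m, 2))
            a_hat = rng.uniform(0, 0.8, m)
            p = LpProblem(gains, gains.T @ a_hat, np.zeros(m), np.ones(m))
            res = solve_min_max(p)
            assert res.status == "optimal"
            assert np.abs(res.torque_residual).max() < 1e-6
            assert res.beta <= a_hat.max() + 1e-7


class TestGridOracle:
    def test_objective_matches_grid_search(self, rng):
        for _ in range(12):
            m = int(rng.integers(1, 4))
            j = int(rng.integers(1, min(m, 2) + 1))
            gains = rng.uniform(5, 40, (m, j))
            a_true = rng.uniform(0.05, 0.6, m)
            p = LpProblem(gains, gains.T @ a_true, np.zeros(m), np.ones(m))
            res = solve_min_max(p)
            assert res.status == "optimal"
            lp_obj = res.activations.max() + p.sum_weight * res.activations.sum()
            grid_obj = grid_search_objective(p, step=1e-3)
            assert abs(lp_obj - grid_obj) <= grid_resolution_bound(p, 1e-3)


class TestBranchSharing:
    def test_equal_gains_plain_mean(self):
        gains = np.array([[10.0], [10.0], [10.0]])
        a = postprocess_branch_sharing(np.array([0.9, 0.0, 0.0]), gains,
                                       [["a", "b", "c"]], ["a", "b", "c"])
        assert np.allclose(a, 0.3)

    def test_torque_preserved_with_unequal_gains(self):
        gains = np.array([[-12.0], [-10.0], [-8.0]])
        a0 = np.array([0.6, 0.1, 0.0])
        a = postprocess_branch_sharing(a0, gains, [["x", "y", "z"]],
                                       ["x", "y", "z"])
        assert a[0] == a[1] == a[2]
        assert gains.T @ a == pytest.approx(gains.T @ a0, abs=1e-9)

    def test_singleton_and_empty_groups_identity(self):
        gains = np.ones((3, 1))
        a0 = np.array([0.1, 0.5, 0.9])
        assert np.array_equal(
            postprocess_branch_sharing(a0, gains, [["a"]], ["a", "b", "c"]), a0)
        assert np.array_equal(
            postprocess_branch_sharing(a0, gains, [], ["a", "b", "c"]), a0)

    def test_reverts_when_torque_not_preservable(self):
        # opposite-sign gains: averaging would change the net torque
        gains = np.array([[10.0], [-10.0]])
        a0 = np.array([0.8, 0.1])
        a = postprocess_branch_sharing(a0, gains, [["a", "b"]], ["a", "b"])
        assert np.array_equal(a, a0)


class TestStepState:
    PARAMS = MuscleParams(name="m", f_max=400.0, l_opt=0.1, l_slack=0.2,
                          joints=(4,))

    def test_frozen_pose_fixed_point(self):
        l_mt = 0.32  # stretched: passive force present
        st = bootstrap_state(l_mt, self.PARAMS)
        for _ in range(30):
            st = step_state(st, l_mt, 0.0, 1 / 120, self.PARAMS)
        from propriosim.muscle import tendon_equilibrium_length
        lm_expected = (l_mt - self.PARAMS.l_slack
                       * tendon_equilibrium_length(st.fm)) / self.PARAMS.l_opt
        assert st.lm == pytest.approx(lm_expected, abs=1e-6)
        assert st.vm == pytest.approx(0.0, abs=1e-9)

    def test_force_feeds_tendon_next_step_not_same(self):
        l_mt = 0.30
        st0 = bootstrap_state(l_mt, self.PARAMS)
        st1 = step_state(st0, l_mt, 1.0, 1 / 120, self.PARAMS)
        # the length at step 1 used the step-0 force, not the new one
        assert st1.lm == pytest.approx(st0.lm)
        st2 = step_state(st1, l_mt, 1.0, 1 / 120, self.PARAMS)
        assert st2.lm < st1.lm  # higher force -> longer tendon -> shorter fiber
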