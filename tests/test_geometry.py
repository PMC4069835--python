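"""Polynomial surrogate surfaces: fitting, evaluation, gradients, R^2."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from propriosim.geometry import (FitError, PolynomialSurface, SampleTable,
                                 fit_surface, goodness_of_fit, term_basis)
from propriosim.synthetic import generate_sample_table, grid_poses


def _table_from_fn(fn, joints, n=60, seed=0):
    rng = np.random.default_rng(seed)
    poses = np.zeros((n, 7))
    for j in joints:
        poses[:, j - 1] = rng.uniform(-1.0, 1.5, n)
    return SampleTable(poses, np.array([fn(p) for p in poses]))


class TestTermBasis:
    def test_single_joint_cubic_has_four_terms(self):
        basis = term_basis((4,))
        assert basis.shape == (4, 7)
        assert sorted(basis[:, 3]) == [0, 1, 2, 3]

    def test_total_degree_capped_at_three(self):
        basis = term_basis((4, 6))
        assert basis.sum(axis=1).max() == 3
        # 1 + 2 + (2 pure quads + 1 cross) + (2 cubes + 2 mixed) = 10
        assert len(basis) == 10

    def test_exponents_only_on_spanned_joints(self):
        basis = term_basis((2, 5))
        unspanned = [0, 2, 3, 5, 6]
        assert not basis[:, unspanned].any()


class TestFitSurface:
    def test_exact_recovery_of_affine_length(self):
        table = _table_from_fn(lambda p: 0.30 - 0.05 * p[3], (4,))
        surf = fit_surface(table, (4,))
        resid = surf.evaluate_many(table.poses) - table.values
        assert np.linalg.norm(resid) < 1e-9
        coeff = dict(zip(map(tuple, surf.exponents), surf.coeffs))
        zero = (0,) * 7
        lin = tuple(1 if j == 3 else 0 for j in range(7))
        assert coeff[zero] == pytest.approx(0.30, abs=1e-10)
        assert coeff[lin] == pytest.approx(-0.05, abs=1e-10)

    def test_closure_any_cubic_recovered(self, rng):
        basis = term_basis((4, 6))
        true_c = rng.normal(size=len(basis))
        target = PolynomialSurface(true_c, basis)
        table = _table_from_fn(target, (4, 6), n=120)
        surf = fit_surface(table, (4, 6))
        assert np.allclose(surf.coeffs, true_c, rtol=1e-8, atol=1e-10)

    def test_idempotent_refit(self, rng):
        table = _table_from_fn(lambda p: 0.3 + 0.02 * np.sin(p[3] + 0.4), (4,))
        surf = fit_surface(table, (4,))
        refit = fit_surface(
            SampleTable(table.poses, surf.evaluate_many(table.poses)), (4,))
        assert np.allclose(refit.coeffs, surf.coeffs, atol=1e-10)

    def test_too_few_rows_rejected(self):
        table = _table_from_fn(lambda p: p[3], (4,), n=3)
        with pytest.raises(FitError, match="rows"):
            fit_surface(table, (4,))

    def test_synthetic_limb_heldout_r2(self, roster):
        for spec in roster:
            train = generate_sample_table(spec, 11, "length")
            surf = fit_surface(train, spec.spanned_joints)
            held = generate_sample_table(spec, 11, "length", midpoints=True)
            assert goodness_of_fit(surf, held) >= 0.99, spec.muscle_id


class TestEvaluate:
    def test_constant_term_at_origin(self):
        surf = PolynomialSurface([1.0, 2.0],
                                 [[0] * 7, [0, 0, 0, 1, 0, 0, 0]])
        assert surf(np.zeros(7)) == 1.0

    def test_hand_arithmetic(self):
        surf = PolynomialSurface([1.0, 2.0],
                                 [[0] * 7, [0, 0, 0, 1, 0, 0, 0]])
        pose = np.zeros(7)
        pose[3] = 0.5
        assert surf(pose) == pytest.approx(2.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(-2, 2), st.floats(-2, 2), st.floats(-1, 1))
    def test_linear_in_coefficients(self, alpha, beta, q4):
        exps = term_basis((4,))
        rng = np.random.default_rng(7)
        a = PolynomialSurface(rng.normal(size=4), exps)
        b = PolynomialSurface(rng.normal(size=4), exps)
        combo = PolynomialSurface(alpha * a.coeffs + beta * b.coeffs, exps)
        pose = np.zeros(7)
        pose[3] = q4
        assert combo(pose) == pytest.approx(alpha * a(pose) + beta * b(pose),
                                            rel=1e-9, abs=1e-9)


class TestGradient:
    def test_constant_surface_zero_gradient(self):
        surf = PolynomialSurface([3.0], [[0] * 7])
        assert np.all(surf.gradient(np.ones(7)) == 0)

    def test_quadratic_derivative(self):
        c = 0.7
        surf = PolynomialSurface([c], [[0, 0, 0, 2, 0, 0, 0]])
        pose = np.zeros(7)
        pose[3] = 1.0
        assert surf.gradient(pose)[3] == pytest.approx(2 * c)

    def test_matches_finite_difference(self, rng):
        exps = term_basis((4, 5, 6))
        surf = PolynomialSurface(rng.normal(size=len(exps)), exps)
        pose = rng.uniform(-0.8, 0.8, 7)
        grad = surf.gradient(pose)
        h = 1e-5
        for j in range(7):
            dp = pose.copy(); dm = pose.copy()
            dp[j] += h; dm[j] -= h
            fd = (surf(dp) - surf(dm)) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_tendon_excursion_consistency(self, roster):
        """Fitted moment arm ~= -d(fitted length)/dq on the sampled grid."""
        for spec in roster:
            train = generate_sample_table(spec, 11, "length")
            lsurf = fit_surface(train, spec.spanned_joints)
            for j in spec.spanned_joints:
                if j not in (4, 5, 6, 7):
                    continue
                mtab = generate_sample_table(spec, 11, "moment_arm", j)
                msurf = fit_surface(mtab, spec.spanned_joints)
                poses = grid_poses(spec.spanned_joints, 7)
                ma = msurf.evaluate_many(poses)
                exc = np.array([-lsurf.gradient(p)[j - 1] for p in poses])
                rms_err = np.sqrt(np.mean((ma - exc) ** 2))
                rms = np.sqrt(np.mean(ma ** 2))
                assert rms_err <= 0.05 * rms, (spec.muscle_id, j)


class TestGoodnessOfFit:
    def test_perfect_fit_gives_one(self):
        table = _table_from_fn(lambda p: 0.2 + 0.1 * p[3], (4,))
        surf = fit_surface(table, (4,))
        assert goodness_of_fit(surf, table) == pytest.approx(1.0, abs=1e-12)

    def test_mean_prediction_gives_zero(self):
        table = _table_from_fn(lambda p: 0.2 + 0.1 * p[3], (4,))
        mean_surf = PolynomialSurface([table.values.mean()], [[0] * 7])
        assert goodness_of_fit(mean_surf, table) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        table = SampleTable(np.zeros((5, 7)), np.full(5, 0.3))
        surf = PolynomialSurface([0.3], [[0] * 7])
        with pytest.raises(ValueError, match="variance"):
            goodness_of_fit(surf, table)


class TestPersistence:
    def test_json_round_trip_bit_stable(self, tmp_path, rng):
        exps = term_basis((4, 6))
        surf = PolynomialSurface(rng.normal(size=len(exps)), exps,
                                 muscle="fcu", target="moment_arm",
                                 joint_index=6)
        path = tmp_path / "fcu.json"
        surf.save(path)
        back = PolynomialSurface.load(path)
        assert np.array_equal(back.coeffs, surf.coeffs)
        assert np.array_equal(back.exponents, surf.exponents)
        assert (back.muscle, back.target, back.joint_index) == ("fcu", "moment_arm", 6)

    def test_sample_table_csv_round_trip(self, tmp_path, rng):
        table = SampleTable(rng.normal(size=(8, 7)), rng.normal(size=8))
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = SampleTable.from_csv(path)
        assert np.array_equal(back.poses, table.poses)
        assert np.array_equal(back.values, table.values)
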