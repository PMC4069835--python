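"""Spindle equilibrium model, firing pipeline, and the ODE reference oracle."""

import numpy as np
import pytest

from propriosim.spindle import (DEFAULT_BAG1, DEFAULT_BAG2, DEFAULT_CHAIN,
                                OdeInstabilityError, SpindleKinematics,
                                SpindleModel, calibrate_rest_lengths,
                                combine_afferents, fiber_equilibrium_tension,
                                fiber_firing_contribution, fusimotor_tension,
                                kinematics_from_lengths,
                                reference_fiber_tension_ode,
                                rescale_gain_human)
from propriosim.validation import spindle_hold_check, spindle_triangle_check


class TestFusimotorTension:
    def test_zero_drive_zero_tension(self):
        assert fusimotor_tension(0.0, DEFAULT_BAG1) == 0.0

    def test_half_saturation_at_corner_rate(self):
        g = fusimotor_tension(DEFAULT_BAG1.gamma_half, DEFAULT_BAG1)
        assert g == pytest.approx(DEFAULT_BAG1.gamma_max / 2)

    def test_saturates(self):
        g = fusimotor_tension(1e6, DEFAULT_BAG1)
        assert g == pytest.approx(DEFAULT_BAG1.gamma_max, rel=1e-6)


class TestEquilibriumTension:
    def test_static_spring_only(self):
        f = DEFAULT_BAG2
        L = 1.05
        t = fiber_equilibrium_tension(SpindleKinematics(L, 0, 0), f)
        assert t == pytest.approx(f.k_pr * (L - f.l_pr0 - f.l_sr0))

    def test_zero_at_rest_length(self):
        f = DEFAULT_BAG2
        L = f.l_pr0 + f.l_sr0
        t = fiber_equilibrium_tension(SpindleKinematics(L, 0, 0), f)
        assert t == pytest.approx(0.0, abs=1e-15)

    def test_lengthening_raises_tension(self):
        f = DEFAULT_BAG1
        static = fiber_equilibrium_tension(SpindleKinematics(1.05, 0, 0), f)
        moving = fiber_equilibrium_tension(SpindleKinematics(1.05, 0.2, 0), f)
        assert moving > static

    def test_velocity_sensitivity_of_peak(self):
        f = DEFAULT_BAG1
        slow = fiber_equilibrium_tension(SpindleKinematics(1.05, 0.05, 0), f)
        fast = fiber_equilibrium_tension(SpindleKinematics(1.05, 0.5, 0), f)
        assert fast > slow

    def test_clamped_at_slack(self):
        f = DEFAULT_BAG2
        t = fiber_equilibrium_tension(SpindleKinematics(0.5, 0, 0), f)
        assert t == 0.0


class TestFiring:
    def test_zero_at_threshold(self):
        f = DEFAULT_BAG1
        t_thr = f.k_sr * (f.l_sr_thresh - f.l_sr0)
        assert fiber_firing_contribution(t_thr, f) == pytest.approx(0.0, abs=1e-9)

    def test_slope_above_threshold(self):
        f = DEFAULT_BAG1
        t_thr = f.k_sr * (f.l_sr_thresh - f.l_sr0)
        dt_ = 0.01
        r = fiber_firing_contribution(t_thr + dt_, f)
        assert r == pytest.approx(f.G * dt_ / f.k_sr, rel=1e-9)

    def test_zero_tension_silent(self):
        assert fiber_firing_contribution(0.0, DEFAULT_BAG1) == 0.0


class TestCombine:
    def test_bag1_absent_passthrough(self):
        r = combine_afferents(0.0, 3.0, 2.0, occlusion=0.156)
        assert r.Ia == pytest.approx(5.0)

    def test_equal_components(self):
        r = combine_afferents(4.0, 2.0, 2.0, occlusion=0.156)
        assert r.Ia == pytest.approx(4.0 * 1.156)

    def test_no_occlusion_is_plain_sum(self):
        r = combine_afferents(3.0, 1.0, 1.0, occlusion=1.0)
        assert r.Ia == pytest.approx(5.0)

    def test_occlusion_bounds(self, rng):
        for _ in range(50):
            p1, b2, ch = rng.uniform(0, 50, 3)
            s = rng.uniform(0, 1)
            ia = combine_afferents(p1, b2, ch, occlusion=s).Ia
            assert max(p1, b2 + ch) - 1e-12 <= ia <= p1 + b2 + ch + 1e-12


class TestHumanRescale:
    def test_divides_by_fifteen(self):
        f = rescale_gain_human(DEFAULT_BAG2)
        assert f.G == pytest.approx(DEFAULT_BAG2.G / 15)
        assert f.G_II == pytest.approx(DEFAULT_BAG2.G_II / 15)

    def test_double_application_guarded(self):
        f = rescale_gain_human(DEFAULT_BAG1)
        with pytest.raises(ValueError, match="already"):
            rescale_gain_human(f)

    def test_fusimotor_step_change_under_30pps(self):
        """A 200 pps fusimotor step changes Ia by < 30 pps after rescaling."""
        model = SpindleModel().rescaled_human()
        kin = SpindleKinematics(1.0, 0.0, 0.0)
        base = model.rates(kin).Ia
        driven = max(model.rates(kin, gamma_static=200.0).Ia,
                     model.rates(kin, gamma_dynamic=200.0).Ia)
        assert driven - base <= 30.0


class TestCalibration:
    def test_zero_static_firing_at_neutral(self):
        model = SpindleModel().calibrated(1.12)
        r = model.rates(SpindleKinematics(1.12, 0.0, 0.0))
        assert r.Ia == 0.0
        assert r.II == 0.0

    def test_identity_at_existing_rest(self):
        f = DEFAULT_BAG2
        cal = calibrate_rest_lengths(f, f.l_pr0 + f.l_sr0)
        assert cal.l_pr0 == pytest.approx(f.l_pr0)
        assert cal.R == pytest.approx(f.R)

    def test_pure_translation_of_static_response(self):
        f = DEFAULT_BAG1
        rest_old = f.l_pr0 + f.l_sr0
        cal = calibrate_rest_lengths(f, 1.1)
        for delta in (0.02, 0.08, 0.15):
            t_new = fiber_equilibrium_tension(
                SpindleKinematics(1.1 + delta, 0.12, 0.0), cal)
            t_old = fiber_equilibrium_tension(
                SpindleKinematics(rest_old + delta, 0.12, 0.0), f)
            assert t_new == pytest.approx(t_old, abs=1e-12)


class TestOdeOracle:
    def test_hold_fixed_point_and_relaxation(self):
        report = spindle_hold_check()
        assert report["max_rel_error"] < 1e-4
        assert max(report["perturbation_decay"].values()) < 0.5

    def test_triangle_stretch_matches_within_ten_percent_of_peak(self):
        report = spindle_triangle_check()
        assert report["ratio"] <= 0.10

    def test_euler_diverges_at_trajectory_rate(self):
        dt = 1.0 / 120.0
        t = np.arange(0, 2, dt)
        L = 1.0 + 0.05 * np.sin(2 * np.pi * 1.0 * t)
        with pytest.raises(OdeInstabilityError):
            reference_fiber_tension_ode(L, dt, DEFAULT_BAG1, dt_inner=dt)

    def test_equilibrium_model_step_size_independent(self):
        """Output at a sample depends only on (L, Ld, Ldd) there, not on the
        step history: sampling the same smooth input at dt and dt/8 yields
        identical rates at the shared samples (the property motivating the
        equilibrium approximation).  A quadratic input makes the central
        differences exact at both rates."""
        model = SpindleModel()
        dt = 1.0 / 120.0
        t1 = np.arange(0, 2.0 + 1e-9, dt)
        t8 = np.arange(0, 2.0 + 1e-9, dt / 8)
        quad = lambda t: 1.0 + 0.02 * t + 0.03 * t ** 2
        ia1, _ = model.rates_series(quad(t1), dt)
        ia8, _ = model.rates_series(quad(t8), dt / 8)
        inner = slice(2, -2)  # one-sided endpoint stencils differ by design
        assert np.allclose(ia1[inner], ia8[::8][inner], atol=1e-9)

    def test_rates_nonnegative_and_finite_over_battery(self):
        model = SpindleModel().rescaled_human()
        dt = 1.0 / 120.0
        t = np.arange(0, 3, dt)
        protocols = [
            np.full_like(t, 1.05),
            1.0 + 0.08 * np.sin(2 * np.pi * 1.5 * t),
            np.clip(0.95 + 0.08 * t, None, 1.1),
        ]
        for L in protocols:
            for gs, gd in [(0, 0), (70, 0), (0, 70)]:
                ia, ii = model.rates_series(L, dt, gs, gd)
                assert np.all(np.isfinite(ia)) and np.all(np.isfinite(ii))
                assert np.all(ia >= 0) and np.all(ii >= 0)

    def test_static_stretch_monotone_ia(self):
        model = SpindleModel()
        rates = [model.rates(SpindleKinematics(L, 0, 0)).Ia
                 for L in np.linspace(0.9, 1.2, 20)]
        assert np.all(np.diff(rates) >= 0)


class TestKinematics:
    def test_backward_scheme_is_causal(self):
        L = np.cumsum(np.random.default_rng(3).normal(size=50)) * 0.001 + 1.0
        full = kinematics_from_lengths(L, 0.01, scheme="backward")
        trunc = kinematics_from_lengths(L[:30], 0.01, scheme="backward")
        for a, b in zip(trunc, full[:30]):
            assert (a.L, a.Ld, a.Ldd) == (b.L, b.Ld, b.Ldd)

    def test_central_scheme_exact_on_quadratic(self):
        dt = 0.01
        t = np.arange(50) * dt
        L = 1.0 + 0.3 * t + 0.2 * t ** 2
        kins = kinematics_from_lengths(L, dt, scheme="central")
        mid = kins[25]
        assert mid.Ld == pytest.approx(0.3 + 0.4 * t[25], rel=1e-9)
        assert mid.Ldd == pytest.approx(0.4, rel=1e-6)
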