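"""Self-contained oracle checks: independent references for each stage.

Each check recomputes a quantity with the package and compares it against an
independent reference — a closed form, an exhaustive search, or a
brute-force ODE integration — and returns a small dict of measurements.
The ``propriosim validate`` subcommand runs the whole battery and the test
suite reuses individual checks.
"""

from __future__ import annotations

import numpy as np

from .geometry import fit_surface, goodness_of_fit
from .gto import GtoParams, design_gto_filter
from .optimization import LpProblem, solve_min_max
from .spindle import (SpindleKinematics, SpindleModel,
                      fiber_equilibrium_tension, fusimotor_tension,
                      reference_fiber_tension_ode)
from .synthetic import (default_muscle_params, default_synthetic_roster,
                        forward_torques, generate_sample_table,
                        make_trajectory)

#: Canonical published coefficients of the discretized GTO dynamics at the
#: 1 kHz / 6 Hz-prewarp design point, printed to 5 decimal places.
GTO_REFERENCE_B = (1.69942, -3.39626, 1.69684)
GTO_REFERENCE_A = (1.0, -1.99780, 0.99780)


def gto_filter_check() -> dict:
    """Design the discrete GTO filter and compare with the canonical values."""
    filt = design_gto_filter(GtoParams())
    dev = max(float(np.abs(filt.b - GTO_REFERENCE_B).max()),
              float(np.abs(filt.a - GTO_REFERENCE_A).max()))
    return {"b": filt.b.tolist(), "a": filt.a.tolist(),
            "max_coeff_deviation": dev, "pass": dev < 5e-6}


def surface_fit_check(n_points: int = 11) -> dict:
    """Fit length surfaces to the synthetic limb; R^2 on held-out midpoints."""
    r2 = {}
    for spec in default_synthetic_roster():
        table = generate_sample_table(spec, n_points, "length")
        surface = fit_surface(table, spec.spanned_joints)
        held_out = generate_sample_table(spec, n_points, "length",
                                         midpoints=True)
        r2[spec.muscle_id] = goodness_of_fit(surface, held_out)
    worst = min(r2.values())
    return {"r2": r2, "min_r2": worst, "pass": worst >= 0.99}


def moment_arm_fit_check(n_points: int = 11) -> dict:
    """Held-out R^2 of moment-arm surfaces, worst case across (muscle, joint)."""
    r2 = {}
    for spec in default_synthetic_roster():
        for j in spec.spanned_joints:
            if j not in (4, 5, 6, 7):
                continue
            table = generate_sample_table(spec, n_points, "moment_arm", j)
            surface = fit_surface(table, spec.spanned_joints)
            held = generate_sample_table(spec, n_points, "moment_arm", j,
                                         midpoints=True)
            r2[f"{spec.muscle_id}_j{j}"] = goodness_of_fit(surface, held)
    worst = min(r2.values())
    return {"r2": r2, "min_r2": worst, "pass": worst >= 0.9}


def spindle_hold_check(dt: float = 1.0 / 120.0, dt_inner: float = 5e-5) -> dict:
    """Equilibrium tension vs the Euler ODE reference on constant-length holds.

    Two properties: (a) the equilibrium tension is a fixed point of the
    dynamic reference — holding a constant length from rest, the ODE tension
    must track the equilibrium value to < 1e-4 relative at every sample;
    (b) perturbed away from equilibrium at constant length, the ODE relaxes
    back toward it (the |v|^0.3 polar damping makes the final approach
    algebraic rather than exponential, so (b) asserts decay, not a tight
    tolerance).
    """
    model = SpindleModel()
    n_hold = 240
    L = np.full(n_hold, 1.08)
    errors = {}
    decay = {}
    for fiber in (model.bag1, model.bag2, model.chain):
        t_eq = fiber_equilibrium_tension(
            SpindleKinematics(float(L[-1]), 0.0, 0.0), fiber)
        t_ode = reference_fiber_tension_ode(L, dt, fiber, dt_inner=dt_inner)
        errors[fiber.fiber_type] = float(np.abs(t_ode - t_eq).max() / abs(t_eq))
        t_pert = reference_fiber_tension_ode(L, dt, fiber, dt_inner=dt_inner,
                                             tension0=1.5 * t_eq)
        e0 = abs(t_pert[0] - t_eq)
        e1 = abs(t_pert[-1] - t_eq)
        decay[fiber.fiber_type] = float(e1 / e0)
    worst = max(errors.values())
    worst_decay = max(decay.values())
    return {"rel_error": errors, "max_rel_error": worst,
            "perturbation_decay": decay,
            "pass": worst < 1e-4 and worst_decay < 0.5}


def spindle_triangle_check(dt: float = 1.0 / 120.0,
                           dt_inner: float = 1e-4) -> dict:
    """Equilibrium vs ODE Ia rates on a slow triangular stretch, no drive.

    Measures the time-averaged absolute discrepancy relative to the peak Ia
    rate; transients at the ramp corners are where the two models differ.
    """
    from .spindle import reference_rates_series
    model = SpindleModel()
    traj = make_trajectory("ramp_hold_triangular", joint=4, duration=8.0,
                           fs=1.0 / dt, amplitude=0.11, velocity=0.05,
                           hold=2.0)
    # map the elbow angle onto a normalized fascicle-length excursion
    ang = traj.q[:, 3]
    L = 0.95 + (ang - ang[0])
    ia_eq, _ = model.rates_series(L, dt, scheme="central")
    ia_ode, _ = reference_rates_series(model, L, dt, dt_inner=dt_inner)
    peak = float(ia_eq.max())
    mean_abs = float(np.mean(np.abs(ia_eq - ia_ode)))
    ratio = mean_abs / peak if peak > 0 else 0.0
    return {"peak_ia": peak, "mean_abs_diff": mean_abs,
            "ratio": ratio, "pass": ratio <= 0.10}


def grid_search_objective(problem: LpProblem, step: float = 1e-3) -> float:
    """Exhaustive-search optimum of the min-max objective.

    Grids the free activation dimensions (muscles minus torque equalities)
    at ``step`` resolution and solves the equality constraints for the rest;
    exact for the small instances it is meant for (<= 3 muscles, <= 2 joints).
    """
    m, j = problem.gains.shape
    free = m - j
    if free < 0:
        raise ValueError("over-determined instance")
    axes = [np.arange(problem.a_min[k], problem.a_max[k] + step / 2, step)
            for k in range(free)]
    if free:
        mesh = np.meshgrid(*axes, indexing="ij")
        a_free = np.column_stack([ax.ravel() for ax in mesh])  # (n, free)
    else:
        a_free = np.zeros((1, 0))
    g_free = problem.gains[:free].T       # (j, free)
    g_dep = problem.gains[free:].T        # (j, j)
    if j > 0:
        try:
            g_dep_inv = np.linalg.inv(g_dep)
        except np.linalg.LinAlgError:
            raise ValueError("dependent gain block is singular")
        rhs = problem.torque_target[None, :] - a_free @ g_free.T
        a_dep = rhs @ g_dep_inv.T                              # (n, j)
    else:
        a_dep = np.zeros((a_free.shape[0], 0))
    ok = np.all((a_dep >= problem.a_min[free:] - 1e-9)
                & (a_dep <= problem.a_max[free:] + 1e-9), axis=1)
    if not ok.any():
        return np.inf
    a = np.hstack([a_free[ok], a_dep[ok]])
    obj = a.max(axis=1, initial=0.0) + problem.sum_weight * a.sum(axis=1)
    return float(obj.min())


def grid_resolution_bound(problem: LpProblem, step: float) -> float:
    """Objective-space resolution of the grid search for one instance.

    Rounding each free activation to the grid (offset <= step) moves each
    equality-solved activation by at most the corresponding row sum of
    |G_dep^-1 G_free| times step; the min-max-plus-weighted-sum objective
    then shifts by at most the bound below.  A factor 2 allows for detours
    around active bounds.
    """
    m, j = problem.gains.shape
    free = m - j
    if free == 0:
        return step  # single feasible point; only float round-off
    g_free = problem.gains[:free].T
    g_dep = problem.gains[free:].T
    rows = np.abs(np.linalg.inv(g_dep) @ g_free).sum(axis=1) if j else np.zeros(0)
    max_coord = max(1.0, float(rows.max(initial=0.0)))
    total = free + float(rows.sum())
    return 2.0 * step * (max_coord + problem.sum_weight * total)


def lp_oracle_check(seed: int = 0, n_instances: int = 25,
                    step: float = 1e-3) -> dict:
    """Solver objective vs exhaustive grid search on random small instances."""
    rng = np.random.default_rng(seed)
    worst_gap = 0.0
    worst_ratio = 0.0
    solved = 0
    for _ in range(n_instances):
        m = int(rng.integers(1, 4))
        j = int(rng.integers(1, min(m, 2) + 1))
        gains = rng.uniform(5.0, 40.0, size=(m, j))
        a_true = rng.uniform(0.05, 0.6, size=m)
        target = gains.T @ a_true  # guaranteed feasible
        problem = LpProblem(gains, target, np.zeros(m), np.ones(m))
        res = solve_min_max(problem)
        if res.status != "optimal":
            continue
        solved += 1
        lp_obj = float(res.activations.max()
                       + problem.sum_weight * res.activations.sum())
        grid_obj = grid_search_objective(problem, step=step)
        gap = abs(lp_obj - grid_obj)
        worst_gap = max(worst_gap, gap)
        worst_ratio = max(worst_ratio,
                          gap / grid_resolution_bound(problem, step))
    return {"instances": n_instances, "solved": solved,
            "max_objective_gap": worst_gap,
            "max_gap_over_resolution": worst_ratio,
            "pass": worst_ratio <= 1.0}


def torque_recovery_check(duration: float = 5.0, fs: float = 120.0,
                          seed: int = 0) -> dict:
    """End-to-end inverse consistency on the synthetic limb.

    Torques forward-generated from prescribed activations must be met by the
    full pipeline with tiny residual and with the min-max criterion no larger
    than the largest prescribed activation.
    """
    from .pipeline import PipelineConfig, fit_surface_set, run_pipeline
    specs = default_synthetic_roster()
    params = default_muscle_params(specs)
    traj = make_trajectory("multi_tone", duration=duration, fs=fs, seed=seed)
    n = len(traj)
    rng = np.random.default_rng(seed + 1)
    acts = np.zeros((n, len(specs)))
    t = traj.time
    for m in rng.choice(len(specs), size=4, replace=False):
        level = rng.uniform(0.15, 0.4)
        f = rng.uniform(0.05, 0.2)
        acts[:, m] = level * 0.5 * (1 + np.sin(2 * np.pi * f * t))
    tau = forward_torques(specs, traj, acts, params)
    traj.tau[:] = tau

    lengths, arms = fit_surface_set(specs)
    # exact analytic geometry for the recovery run: use fitted surfaces would
    # add surrogate error on top of the optimization check
    from .geometry import PolynomialSurface
    config = PipelineConfig(params, lengths, arms)
    _install_analytic_geometry(config, specs)
    out = run_pipeline(traj, config)
    max_resid = float(out[[c for c in out.columns
                           if c.startswith("residual")]].abs().max().max())
    beta_margin = float((acts.max(axis=1) - out["beta"].to_numpy()).min())
    return {"max_torque_residual": max_resid,
            "min_beta_margin": beta_margin,
            "pass": max_resid < 1e-6 and beta_margin >= 0.0}


def _install_analytic_geometry(config, specs) -> None:
    """Swap the fitted surfaces for exact closed-form geometry callables."""
    from .synthetic import analytic_length, analytic_moment_arm

    class _Len:
        def __init__(self, spec):
            self.spec = spec

        def __call__(self, pose):
            return analytic_length(self.spec, pose)

    class _Arm:
        def __init__(self, spec, j):
            self.spec, self.j = spec, j

        def __call__(self, pose):
            return analytic_moment_arm(self.spec, pose, self.j)

    config.length_surfaces = {s.muscle_id: _Len(s) for s in specs}
    config.ma_surfaces = {(s.muscle_id, j): _Arm(s, j)
                          for s in specs for j in s.spanned_joints
                          if j in config.torque_joints}


def run_battery(seed: int = 0) -> dict:
    """Run every oracle check; returns a report dict with an overall flag."""
    report = {
        "gto_filter": gto_filter_check(),
        "surface_fit": surface_fit_check(),
        "moment_arm_fit": moment_arm_fit_check(),
        "spindle_hold": spindle_hold_check(),
        "spindle_triangle": spindle_triangle_check(),
        "lp_oracle": lp_oracle_check(seed),
        "torque_recovery": torque_recovery_check(seed=seed),
    }
    report["pass"] = all(v["pass"] for k, v in report.items() if k != "pass")
    return report
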