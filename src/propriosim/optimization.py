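"""Per-timestep static optimization of muscle activations (min-max LP).

Muscle redundancy — many muscles crossing each resolved joint — means the
measured joint torques do not determine activations uniquely.  Each timestep
is resolved by the min-max criterion: minimize the largest activation,
linearized with an auxiliary criterion variable beta,

    minimize  beta + w * sum_m a_m          (w = 0.01 by default)
    s.t.      a_m <= beta                    for every muscle
              sum_m gain_mj * a_m = T*_j - passive_j   for each torque joint
              a_min_m <= a_m <= a_max_m,  0 <= beta <= 1,

where gain_mj = f_l * f_v * R_mj * F_o is the torque each muscle produces per
unit activation about joint j at the current kinematics.  The small summed-
activation term breaks the criterion's indifference to activations below the
maximum.  Activation first-order dynamics are folded in as per-step bounds
[a_min, a_max] reachable from the previous activation within dt given the
activation/deactivation time constants (15 ms / 50 ms).

Only the elbow and wrist joints (4-7 by default) carry torque constraints;
the shoulder angles still shape muscle lengths and moment arms but their
torques are not resolved.  Infeasible steps are re-solved with penalized
per-joint slack so a streaming application degrades gracefully instead of
halting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

TAU_ACT = 0.015    # activation time constant [s]
TAU_DEACT = 0.050  # deactivation time constant [s]


def activation_bounds(a_prev, dt: float, tau_act: float = TAU_ACT,
                      tau_deact: float = TAU_DEACT):
    """Feasible activation range reachable from ``a_prev`` after ``dt`` [s].

    Obtained from the first-order activation dynamics with excitation driven
    to 0 (lower bound) or 1 (upper bound), then clamped into [0, 1]:

        a_min = a - dt * a * (0.5 + 1.5 a) / tau_deact
        a_max = a + dt * (1 - a) / (tau_act * (0.5 + 1.5 a))
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a = np.asarray(a_prev, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("previous activation outside [0, 1]")
    tau_scale = 0.5 + 1.5 * a
    a_min = a - dt * a * tau_scale / tau_deact
    a_max = a + dt * (1.0 - a) / (tau_act * tau_scale)
    return np.clip(a_min, 0.0, 1.0), np.clip(a_max, 0.0, 1.0)


@dataclass
class LpProblem:
    """Assembled min-max LP for one timestep.

    Variables are the muscle activations followed by the criterion variable
    beta.  ``gains`` is (n_muscles, n_joints); ``torque_target`` already has
    the passive contribution removed.
    """

    gains: np.ndarray
    torque_target: np.ndarray
    a_min: np.ndarray
    a_max: np.ndarray
    sum_weight: float = 0.01

    def __post_init__(self):
        self.gains = np.atleast_2d(np.asarray(self.gains, dtype=float))
        self.torque_target = np.asarray(self.torque_target, dtype=float).ravel()
        self.a_min = np.asarray(self.a_min, dtype=float).ravel()
        self.a_max = np.asarray(self.a_max, dtype=float).ravel()
        m, j = self.gains.shape
        if self.torque_target.shape != (j,):
            raise ValueError("torque target length mismatch")
        if self.a_min.shape != (m,) or self.a_max.shape != (m,):
            raise ValueError("bounds length mismatch")
        if np.any(self.a_min > self.a_max + 1e-12):
            raise ValueError("a_min exceeds a_max")
        if not np.all(np.isfinite(self.gains)):
            raise ValueError("gains must be finite")

    @property
    def n_muscles(self) -> int:
        return self.gains.shape[0]

    @property
    def n_joints(self) -> int:
        return self.gains.shape[1]

    def matrices(self):
        """(c, A_ub, b_ub, A_eq, b_eq, bounds) in scipy.linprog form."""
        m, j = self.gains.shape
        c = np.concatenate([np.full(m, self.sum_weight), [1.0]])
        a_ub = np.hstack([np.eye(m), -np.ones((m, 1))])
        b_ub = np.zeros(m)
        a_eq = np.hstack([self.gains.T, np.zeros((j, 1))])
        b_eq = self.torque_target.copy()
        bounds = [(lo, hi) for lo, hi in zip(self.a_min, self.a_max)]
        bounds.append((0.0, 1.0))  # beta
        return c, a_ub, b_ub, a_eq, b_eq, bounds


@dataclass
class OptimizationResult:
    activations: np.ndarray
    beta: float
    status: str                       # "optimal" | "relaxed" | "infeasible"
    torque_residual: np.ndarray       # achieved - target, per joint [N m]
    slack_penalty_used: float = 0.0


def build_lp(gains, passive_torque, torque_measured, a_min, a_max,
             sum_weight: float = 0.01) -> LpProblem:
    """Assemble the LP; the equality target is measured minus passive torque."""
    passive = np.asarray(passive_torque, dtype=float).ravel()
    target = np.asarray(torque_measured, dtype=float).ravel() - passive
    return LpProblem(gains, target, a_min, a_max, sum_weight=sum_weight)


def solve_min_max(problem: LpProblem, slack_penalty: float = 1e3,
                  tol: float = 1e-9) -> OptimizationResult:
    """Solve the min-max LP (HiGHS); relax with penalized slack if infeasible."""
    c, a_ub, b_ub, a_eq, b_eq, bounds = problem.matrices()

    # A joint whose gains are all ~zero but whose target torque is not cannot
    # be balanced; go straight to the relaxed solve.
    degenerate = np.any(
        (np.abs(problem.gains).max(axis=0) < 1e-12)
        & (np.abs(b_eq) > 1e-12))

    if not degenerate:
        res = linprog(c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq,
                      bounds=bounds, method="highs")
        if res.status == 0:
            a = res.x[:-1]
            residual = problem.gains.T @ a - b_eq
            return OptimizationResult(a, float(res.x[-1]), "optimal",
                                      residual)
        if res.status not in (2,):  # not plain infeasibility
            logger.error("LP solver failure (%s); problem: gains=%s target=%s",
                         res.message, problem.gains, b_eq)
            if res.status != 2:
                raise RuntimeError(f"LP solver failure: {res.message}")

    # Relaxed solve: per-joint slack s+ and s- penalized in the objective.
    m, j = problem.gains.shape
    c2 = np.concatenate([c, np.full(2 * j, slack_penalty)])
    a_ub2 = np.hstack([a_ub, np.zeros((m, 2 * j))])
    a_eq2 = np.hstack([a_eq, np.eye(j), -np.eye(j)])
    bounds2 = bounds + [(0, None)] * (2 * j)
    res = linprog(c2, A_ub=a_ub2, b_ub=b_ub, A_eq=a_eq2, b_eq=b_eq,
                  bounds=bounds2, method="highs")
    if res.status != 0:
        logger.error("relaxed LP failed (%s); gains=%s target=%s",
                     res.message, problem.gains, b_eq)
        return OptimizationResult(problem.a_min.copy(), float(problem.a_min.max()),
                                  "infeasible", -b_eq.copy(), slack_penalty)
    a = res.x[:m]
    residual = problem.gains.T @ a - b_eq
    status = "optimal" if np.abs(residual).max() < 1e-6 else "relaxed"
    return OptimizationResult(a, float(res.x[m]), status, residual,
                              slack_penalty if status == "relaxed" else 0.0)


def postprocess_branch_sharing(activations, gains, branch_groups,
                               muscle_names, tol: float = 1e-6) -> np.ndarray:
    """Average activations within anatomical branch groups, preserving torque.

    The min-max criterion is indifferent to how load is shared among parallel
    branches of one muscle (e.g. the three triceps heads), which can leave one
    branch fully loaded and its twins idle.  Within each group the activations
    are replaced by their torque-capacity-weighted mean (plain mean when the
    branches' gains are equal), which preserves the group's torque
    contribution exactly when the branches act about the same joints.  If the
    overall torque residual nevertheless grows beyond ``tol`` the group is
    reverted with a warning.
    """
    a = np.asarray(activations, dtype=float).copy()
    gains = np.atleast_2d(np.asarray(gains, dtype=float))
    name_to_idx = {n: i for i, n in enumerate(muscle_names)}
    base_torque = gains.T @ a
    for group in branch_groups or []:
        idx = [name_to_idx[n] for n in group if n in name_to_idx]
        if len(idx) < 2:
            continue
        w = np.abs(gains[idx]).sum(axis=1)
        if w.sum() <= 0 or np.allclose(w, w[0]):
            w = np.ones(len(idx))
        mean = float(np.dot(w, a[idx]) / w.sum())
        old = a[idx].copy()
        a[idx] = mean
        if np.abs(gains.T @ a - base_torque).max() > tol:
            a[idx] = old
            logger.warning("branch group %s not averaged: torque residual "
                           "would exceed %.1e", group, tol)
    return np.clip(a, 0.0, 1.0)


# --- per-step state update -------------------------------------------------

from .muscle import (MuscleParams, MuscleState, fiber_length_from_path,
                     force_coefficients, tendon_equilibrium_length)


def bootstrap_state(l_mt: float, params: MuscleParams,
                    n_iter: int = 20) -> MuscleState:
    """Initial state at a pose: a=0, v=0, passive-force/tendon fixed point."""
    f = 0.0
    lm = fiber_length_from_path(l_mt, f, params)
    for _ in range(n_iter):
        lm = fiber_length_from_path(l_mt, f, params)
        _, _, fp = force_coefficients(lm, 0.0, params)
        if abs(fp - f) < 1e-12:
            f = fp
            break
        f = fp
    return MuscleState(lm=lm, vm=0.0, fm=f, act=0.0, lmt=l_mt)


def step_state(prev: MuscleState, l_mt: float, activation: float, dt: float,
               params: MuscleParams) -> MuscleState:
    """Advance one muscle's state to the next sample.

    The tendon length estimate uses the previous step's normalized force
    (previous-iteration state feeding).  The fiber velocity is the backward
    difference of the musculotendon path length scaled by 1/v_max (a
    rigid-tendon velocity estimate): differencing the tendon-corrected fiber
    length instead would couple the force-velocity curve to the one-step-
    delayed tendon state and that loop is unstable for short-fibered,
    long-tendoned muscles at ordinary sample rates.
    """
    lm = fiber_length_from_path(l_mt, prev.fm, params)
    vm = (l_mt - prev.lmt) / (dt * params.v_max)
    fl, fv, fp = force_coefficients(lm, vm, params)
    f_norm = activation * fl * fv + fp
    return MuscleState(lm=lm, vm=vm, fm=f_norm, act=activation, lmt=l_mt)
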