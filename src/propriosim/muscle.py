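"""Dimensionless Hill-type muscle mechanics with an equilibrium elastic tendon.

Each muscle is a standard three-component Hill model at zero pennation,
normalized so one set of curves serves every muscle: fiber length by the
optimal fiber length L_o, tendon length by the tendon slack length L_s,
force by the maximum isometric force F_o, and shortening velocity by
v_max = vmax_factor * L_o per second (default 7, midway between slow- and
fast-twitch estimates).  Active force is a * f_l(L) * f_v(v), passive force
is f_p(L), and joint torque is the moment-arm-weighted sum of muscle forces.

The series tendon is handled in equilibrium rather than as an ODE: the
normalized tendon length under a given normalized force follows a cubic fit
to the tendon strain curve,

    L_T = 0.04879 F^3 - 0.1009 F^2 + 0.1003 F + 1,

so fiber length is obtained by subtracting the loaded tendon length from the
musculotendon path length with no differential equation to integrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

#: Cubic fit to the normalized tendon strain curve (highest power first).
TENDON_CUBIC = (0.04879, -0.1009, 0.1003, 1.0)


@dataclass(frozen=True)
class CurveConstants:
    """Shape constants of the normalized Hill curves (conventional defaults)."""

    gamma_fl: float = 0.45   # width of the Gaussian active force-length curve
    k_pe: float = 5.0        # passive exponential shape
    eps0: float = 0.6        # passive strain at one normalized force
    a_f: float = 0.25        # Hill force-velocity curvature (shortening)
    f_len: float = 1.4       # eccentric force plateau (> 1)


@dataclass(frozen=True)
class MuscleParams:
    """Scaling constants of one muscle.

    joints are 1-based indices of the spanned degrees of freedom.
    """

    name: str
    f_max: float                 # maximum isometric force [N]
    l_opt: float                 # optimal fiber length [m]
    l_slack: float               # tendon slack length [m]
    vmax_factor: float = 7.0     # v_max = vmax_factor * l_opt [1/s]
    joints: tuple[int, ...] = ()
    curves: CurveConstants = field(default_factory=CurveConstants)

    def __post_init__(self):
        if min(self.f_max, self.l_opt, self.l_slack, self.vmax_factor) <= 0:
            raise ValueError(f"muscle {self.name!r}: scaling constants must be > 0")
        if self.curves.f_len <= 1:
            raise ValueError("eccentric plateau f_len must exceed 1")

    @property
    def v_max(self) -> float:
        """Maximum shortening velocity [m/s]."""
        return self.vmax_factor * self.l_opt


@dataclass
class MuscleState:
    """Per-timestep normalized state of one muscle."""

    lm: float = 1.0    # normalized fiber length [-]
    vm: float = 0.0    # normalized fiber velocity [-], positive = lengthening
    fm: float = 0.0    # normalized force [-]
    act: float = 0.0   # activation in [0, 1]
    lmt: float = 0.0   # musculotendon path length [m] (velocity estimate)


def tendon_equilibrium_length(f_norm):
    """Normalized tendon length under normalized force (equilibrium cubic)."""
    f = np.asarray(f_norm, dtype=float)
    if np.any(f < 0):
        raise ValueError("normalized tendon force must be >= 0")
    out = np.polyval(TENDON_CUBIC, f)
    return float(out) if np.isscalar(f_norm) or f.ndim == 0 else out


def fiber_length_from_path(l_mt: float, f_norm: float,
                           params: MuscleParams) -> float:
    """Normalized fiber length from the musculotendon path length [m].

    Subtracts the loaded tendon length L_s * L_T(F) and normalizes by L_o.
    """
    lm = (l_mt - params.l_slack * tendon_equilibrium_length(f_norm)) / params.l_opt
    if lm <= 0:
        raise ValueError(
            f"muscle {params.name!r}: nonpositive fiber length "
            f"(path {l_mt:.4f} m shorter than loaded tendon)")
    return lm


def active_force_length(lm, c: CurveConstants = CurveConstants()):
    """Gaussian active force-length curve, peak 1 at optimal length."""
    lm = np.asarray(lm, dtype=float)
    return np.exp(-((lm - 1.0) ** 2) / c.gamma_fl)


def passive_force_length(lm, c: CurveConstants = CurveConstants()):
    """Exponential parallel-elastic curve, zero at/below optimal length."""
    lm = np.asarray(lm, dtype=float)
    raw = (np.exp(c.k_pe * (lm - 1.0) / c.eps0) - 1.0) / (np.exp(c.k_pe) - 1.0)
    return np.where(lm > 1.0, raw, 0.0)


def force_velocity(vm, c: CurveConstants = CurveConstants()):
    """Hill force-velocity curve.

    Shortening branch (v in [-1, 0]): (1+v)/(1 - v/a_f), zero at the maximum
    shortening velocity; clamped to 0 below v = -1.  Lengthening branch:
    smooth exponential saturation to the eccentric plateau f_len,
    C1-continuous at v = 0 (both branches have slope (1 + 1/a_f) there).
    """
    vm = np.asarray(vm, dtype=float)
    slope0 = 1.0 + 1.0 / c.a_f
    k_ecc = slope0 / (c.f_len - 1.0)
    short = (1.0 + vm) / (1.0 - vm / c.a_f)
    ecc = c.f_len - (c.f_len - 1.0) * np.exp(-k_ecc * vm)
    out = np.where(vm >= 0, ecc, np.where(vm <= -1.0, 0.0, short))
    return out


def force_coefficients(lm: float, vm: float, params: MuscleParams):
    """(f_l, f_v, f_p) at the given normalized length and velocity."""
    if lm <= 0:
        raise ValueError("normalized fiber length must be > 0")
    c = params.curves
    return (float(active_force_length(lm, c)),
            float(force_velocity(vm, c)),
            float(passive_force_length(lm, c)))


def muscle_force(state: MuscleState, params: MuscleParams) -> float:
    """Muscle force [N]; also stores the normalized force back on the state."""
    fl, fv, fp = force_coefficients(state.lm, state.vm, params)
    f_norm = state.act * fl * fv + fp
    state.fm = f_norm
    return f_norm * params.f_max


def joint_torques(forces, moment_arms) -> np.ndarray:
    """Torque about each resolved joint: T_j = sum_m F_m * R_mj.

    ``forces`` is (n_muscles,) [N]; ``moment_arms`` is (n_muscles, n_joints) [m].
    """
    forces = np.asarray(forces, dtype=float)
    moment_arms = np.atleast_2d(np.asarray(moment_arms, dtype=float))
    if moment_arms.shape[0] != forces.shape[0]:
        raise ValueError("forces and moment-arm rows differ")
    return forces @ moment_arms


# --- parameter-table I/O ---------------------------------------------------

def muscles_to_yaml(muscles: list[MuscleParams], path) -> None:
    recs = [
        {
            "name": m.name,
            "F_o": float(m.f_max),
            "L_o": float(m.l_opt),
            "L_Ts": float(m.l_slack),
            "vmax_factor": float(m.vmax_factor),
            "joints": [int(j) for j in m.joints],
        }
        for m in muscles
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"muscles": recs}, fh, sort_keys=False)


def muscles_from_yaml(path) -> list[MuscleParams]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = []
    for rec in doc["muscles"]:
        out.append(MuscleParams(
            name=rec["name"], f_max=rec["F_o"], l_opt=rec["L_o"],
            l_slack=rec["L_Ts"], vmax_factor=rec.get("vmax_factor", 7.0),
            joints=tuple(rec.get("joints", ()))))
    return out


def with_curves(params: MuscleParams, **kwargs) -> MuscleParams:
    """Copy of ``params`` with updated curve constants."""
    return replace(params, curves=replace(params.curves, **kwargs))
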