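"""Analytic synthetic limb: closed-form geometry and trajectories for testing.

A full 3D musculoskeletal model is not needed to exercise the pipeline: this
module defines muscles whose musculotendon length is an explicit function of
the joint angles, so lengths, moment arms (exact negative partial
derivatives) and inverse-consistent joint torques are all known in closed
form.  Two kinds of per-joint length terms are available:

* constant-pulley: length term -sign * r * q_j, i.e. a constant moment arm
  sign * r (a tendon over an ideal pulley);
* sinusoidal wrap: length term A * sin(q_j + phi), moment arm
  -A * cos(q_j + phi), mimicking a tendon wrapping over a bony prominence.
  The sinusoid is deliberately outside the cubic polynomial model class, so
  fitting surrogate surfaces to it is a genuine approximation test.

The default roster mirrors a 17-muscle elbow/wrist musculature with a few
biarticular muscles that also span a shoulder angle (so shoulder pose
modulates elbow muscle lengths, as for the biceps and long triceps head).
All generated fixtures are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import DEFAULT_JOINT_RANGES, N_JOINTS, SampleTable, as_pose
from .muscle import MuscleParams, MuscleState, force_coefficients
from .optimization import bootstrap_state, step_state


@dataclass(frozen=True)
class PulleyTerm:
    joint: int       # 1-based
    radius: float    # [m] > 0
    sign: int = 1    # +1: muscle shortens as q increases (flexor-like)

    def length(self, q: float) -> float:
        return -self.sign * self.radius * q

    def moment_arm(self, q: float) -> float:
        return self.sign * self.radius


@dataclass(frozen=True)
class WrapTerm:
    joint: int        # 1-based
    amplitude: float  # [m]; sign sets flexor/extensor action
    phase: float = 0.0

    def length(self, q: float) -> float:
        return self.amplitude * np.sin(q + self.phase)

    def moment_arm(self, q: float) -> float:
        return -self.amplitude * np.cos(q + self.phase)


@dataclass(frozen=True)
class SyntheticMuscleSpec:
    muscle_id: str
    base_length: float                       # [m]
    terms: tuple = ()                        # PulleyTerm | WrapTerm

    def __post_init__(self):
        if not self.terms:
            raise ValueError(f"{self.muscle_id}: needs at least one joint term")

    @property
    def spanned_joints(self) -> tuple[int, ...]:
        return tuple(sorted({t.joint for t in self.terms}))


def analytic_length(spec: SyntheticMuscleSpec, pose) -> float:
    """Closed-form musculotendon length [m]."""
    q = as_pose(pose)
    length = spec.base_length + sum(t.length(q[t.joint - 1]) for t in spec.terms)
    if length <= 0:
        raise ValueError(f"{spec.muscle_id}: nonpositive length at pose {q}")
    return float(length)


def analytic_moment_arm(spec: SyntheticMuscleSpec, pose, joint: int) -> float:
    """Closed-form moment arm about 1-based ``joint`` [m] (= -dL/dq_j)."""
    q = as_pose(pose)
    return float(sum(t.moment_arm(q[t.joint - 1])
                     for t in spec.terms if t.joint == joint))


def analytic_moment_arms(spec: SyntheticMuscleSpec, pose,
                         joints) -> np.ndarray:
    return np.array([analytic_moment_arm(spec, pose, j) for j in joints])


def grid_poses(spanned_joints, n_points: int = 11,
               joint_ranges: np.ndarray = DEFAULT_JOINT_RANGES,
               neutral: np.ndarray | None = None,
               midpoints: bool = False) -> np.ndarray:
    """Full-factorial pose grid over the spanned joints; others at neutral.

    With ``midpoints=True`` the grid nodes sit halfway between the default
    nodes (held-out validation poses).
    """
    if neutral is None:
        neutral = joint_ranges.mean(axis=1)
    axes = []
    for j in spanned_joints:
        lo, hi = joint_ranges[j - 1]
        pts = np.linspace(lo, hi, n_points)
        if midpoints:
            pts = 0.5 * (pts[:-1] + pts[1:])
        axes.append(pts)
    mesh = np.meshgrid(*axes, indexing="ij")
    n = mesh[0].size if mesh else 1
    poses = np.tile(neutral, (n, 1))
    for ax, j in zip(mesh, spanned_joints):
        poses[:, j - 1] = ax.ravel()
    return poses


def generate_sample_table(spec: SyntheticMuscleSpec, n_points: int = 11,
                          target: str = "length",
                          joint_index: int | None = None,
                          joint_ranges: np.ndarray = DEFAULT_JOINT_RANGES,
                          midpoints: bool = False) -> SampleTable:
    """Sweep the spanned joints and tabulate exact lengths or moment arms."""
    poses = grid_poses(spec.spanned_joints, n_points, joint_ranges,
                       midpoints=midpoints)
    if target == "length":
        values = np.array([analytic_length(spec, p) for p in poses])
    elif target == "moment_arm":
        if joint_index is None:
            raise ValueError("moment-arm table needs a joint_index")
        values = np.array([analytic_moment_arm(spec, p, joint_index)
                           for p in poses])
    else:
        raise ValueError(f"unknown target {target!r}")
    return SampleTable(poses, values, muscle=spec.muscle_id, target=target,
                       joint_index=joint_index)


# --- trajectories ----------------------------------------------------------

@dataclass
class Trajectory:
    """Uniform-rate series of joint angles and distal joint torques."""

    time: np.ndarray    # (n,) [s]
    q: np.ndarray       # (n, 7) [rad]
    tau: np.ndarray     # (n, 4) [N m] about joints 4-7

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        self.tau = np.atleast_2d(np.asarray(self.tau, dtype=float))
        n = len(self.time)
        if self.q.shape != (n, N_JOINTS) or self.tau.shape != (n, 4):
            raise ValueError("trajectory arrays are inconsistent")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    def __len__(self) -> int:
        return len(self.time)


def make_trajectory(kind: str, joint: int = 4, duration: float = 30.0,
                    fs: float = 120.0, amplitude: float = 0.5,
                    frequency: float = 0.5, velocity: float = 0.5,
                    hold: float = 1.0, offset: float | None = None,
                    neutral: np.ndarray | None = None,
                    seed: int = 0) -> Trajectory:
    """Deterministic single- or multi-joint test motions with zero torques.

    Kinds: ``hold`` (static pose), ``ramp_hold_triangular`` (ramp up at
    ``velocity`` rad/s, hold, ramp down — the classic spindle stretch
    protocol), ``sinusoid`` (angle amplitude/frequency about the offset), and
    ``multi_tone`` (seeded sum of three incommensurate sinusoids on every
    joint, a stand-in for naturalistic motion).
    """
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    if neutral is None:
        neutral = DEFAULT_JOINT_RANGES.mean(axis=1)
    q = np.tile(neutral, (n, 1))
    lo, hi = DEFAULT_JOINT_RANGES[joint - 1]
    base = neutral[joint - 1] if offset is None else offset

    if kind == "hold":
        q[:, joint - 1] = base
    elif kind == "ramp_hold_triangular":
        ramp_t = amplitude / velocity
        angle = np.full(n, base)
        rising = t < ramp_t
        angle[rising] = base + velocity * t[rising]
        holding = (t >= ramp_t) & (t < ramp_t + hold)
        angle[holding] = base + amplitude
        falling = t >= ramp_t + hold
        angle[falling] = np.maximum(
            base, base + amplitude - velocity * (t[falling] - ramp_t - hold))
        q[:, joint - 1] = angle
    elif kind == "sinusoid":
        q[:, joint - 1] = base + amplitude * np.sin(2 * np.pi * frequency * t)
    elif kind == "multi_tone":
        rng = np.random.default_rng(seed)
        for j in range(N_JOINTS):
            jl, jh = DEFAULT_JOINT_RANGES[j]
            span = 0.25 * (jh - jl)
            freqs = rng.uniform(0.1, 1.3, size=3)
            phases = rng.uniform(0, 2 * np.pi, size=3)
            amps = span * rng.dirichlet(np.ones(3))
            q[:, j] = neutral[j] + sum(
                a * np.sin(2 * np.pi * f * t + p)
                for a, f, p in zip(amps, freqs, phases))
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")

    np.clip(q, DEFAULT_JOINT_RANGES[:, 0], DEFAULT_JOINT_RANGES[:, 1], out=q)
    return Trajectory(t, q, np.zeros((n, 4)))


# --- inverse-consistency harness ------------------------------------------

def forward_torques(specs: list[SyntheticMuscleSpec], trajectory: Trajectory,
                    activations: np.ndarray,
                    muscle_params: list[MuscleParams],
                    torque_joints=(4, 5, 6, 7)) -> np.ndarray:
    """Torque series produced by prescribed activations on the analytic limb.

    Runs the same per-step state recursion as the pipeline (previous-step
    force feeding the tendon-length estimate, backward-difference velocity)
    but with activations given, so feeding the returned torques back through
    the full inverse pipeline is an end-to-end recovery test.
    """
    acts = np.atleast_2d(np.asarray(activations, dtype=float))
    if acts.shape != (len(trajectory), len(specs)):
        raise ValueError("activations must be (n_samples, n_muscles)")
    if np.any((acts < 0) | (acts > 1)):
        raise ValueError("activations must lie in [0, 1]")
    dt = trajectory.dt
    torques = np.zeros((len(trajectory), len(torque_joints)))
    states: list[MuscleState] = [
        bootstrap_state(analytic_length(s, trajectory.q[0]), p)
        for s, p in zip(specs, muscle_params)]
    for i in range(len(trajectory)):
        pose = trajectory.q[i]
        for m, (spec, params) in enumerate(zip(specs, muscle_params)):
            l_mt = analytic_length(spec, pose)
            if i > 0:
                states[m] = step_state(states[m], l_mt, acts[i, m], dt, params)
            else:
                states[m].act = acts[0, m]
                fl, fv, fp = force_coefficients(states[m].lm, 0.0, params)
                states[m].fm = acts[0, m] * fl * fv + fp
            force = states[m].fm * params.f_max
            arms = analytic_moment_arms(spec, pose, torque_joints)
            torques[i] += force * arms
    return torques


# --- default roster --------------------------------------------------------

def default_synthetic_roster() -> list[SyntheticMuscleSpec]:
    """17 muscles over the elbow/wrist with biarticular shoulder coupling.

    Flexor-like muscles have positive moment arms about their joints
    (amplitude < 0 on the wrap term puts the length minimum near full
    flexion); extensors the opposite.  Amplitudes keep lengths within about
    +/-20% of the base path length across the ranges of motion.
    """
    # Phases for the resolved joints (4-7) are chosen so q + phi stays inside
    # (-pi/2, pi/2) across the joint range: each muscle's moment arm keeps one
    # sign over the workspace (flexors stay flexors).  Shoulder terms (joint 1,
    # unresolved) only modulate biarticular lengths and may flip freely.
    w = WrapTerm
    return [
        SyntheticMuscleSpec("biceps_long", 0.36, (
            w(1, -0.012, 0.40), w(4, -0.032, -1.10), w(5, -0.008, 0.03))),
        SyntheticMuscleSpec("biceps_short", 0.33, (
            w(1, -0.010, 0.70), w(4, -0.030, -0.95), w(5, -0.007, -0.03))),
        SyntheticMuscleSpec("brachialis", 0.14, (w(4, -0.028, -1.25),)),
        SyntheticMuscleSpec("brachioradialis", 0.26, (w(4, -0.040, -0.80),)),
        SyntheticMuscleSpec("triceps_long", 0.34, (
            w(1, 0.011, 0.55), w(4, 0.024, -1.05))),
        SyntheticMuscleSpec("triceps_lateral", 0.22, (w(4, 0.022, -0.90),)),
        SyntheticMuscleSpec("triceps_medial", 0.20, (w(4, 0.022, -1.20),)),
        SyntheticMuscleSpec("anconeus", 0.10, (w(4, 0.012, -1.00),)),
        SyntheticMuscleSpec("pronator_teres", 0.16, (
            w(4, -0.012, -1.15), w(5, -0.014, 0.02))),
        SyntheticMuscleSpec("pronator_quadratus", 0.06, (w(5, -0.011, -0.04),)),
        SyntheticMuscleSpec("supinator", 0.09, (w(5, 0.013, 0.05),)),
        SyntheticMuscleSpec("fcr", 0.27, (w(6, -0.016, 0.20), w(7, -0.007, 0.30))),
        SyntheticMuscleSpec("fcu", 0.28, (w(6, -0.018, -0.15), w(7, 0.009, 0.25))),
        SyntheticMuscleSpec("ecrl", 0.30, (w(6, 0.015, 0.10), w(7, -0.008, -0.40))),
        SyntheticMuscleSpec("ecrb", 0.28, (w(6, 0.014, 0.25), w(7, -0.006, -0.20))),
        SyntheticMuscleSpec("ecu", 0.29, (w(6, 0.016, -0.30), w(7, 0.010, 0.45))),
        SyntheticMuscleSpec("edci", 0.31, (w(6, 0.013, 0.05), w(7, -0.004, 0.60))),
    ]


def default_muscle_params(
        specs: list[SyntheticMuscleSpec] | None = None,
        neutral: np.ndarray | None = None) -> list[MuscleParams]:
    """Hill-model constants matched to the synthetic roster.

    Optimal fiber lengths and maximum forces are typical upper-limb values
    (elbow muscles stronger and longer-fibered than wrist muscles); tendon
    slack lengths are set so each fiber sits at its optimal length at the
    neutral pose.
    """
    if specs is None:
        specs = default_synthetic_roster()
    if neutral is None:
        neutral = DEFAULT_JOINT_RANGES.mean(axis=1)
    f_by_joint = {1: 600.0, 4: 600.0, 5: 350.0, 6: 250.0, 7: 250.0}
    l_by_joint = {1: 0.12, 4: 0.10, 5: 0.05, 6: 0.06, 7: 0.06}
    out = []
    for spec in specs:
        main = 4 if 4 in spec.spanned_joints else spec.spanned_joints[-1]
        l_opt = l_by_joint[main]
        l_mt0 = analytic_length(spec, neutral)
        l_slack = l_mt0 - l_opt
        if l_slack <= 0.01:
            l_opt = 0.6 * l_mt0
            l_slack = l_mt0 - l_opt
        out.append(MuscleParams(
            name=spec.muscle_id, f_max=f_by_joint[main], l_opt=l_opt,
            l_slack=l_slack, joints=spec.spanned_joints))
    return out


#: Default anatomical branch groups for load-sharing postprocessing.
DEFAULT_BRANCH_GROUPS = [["triceps_long", "triceps_lateral", "triceps_medial"]]


# --- spec YAML I/O ---------------------------------------------------------

def specs_to_yaml(specs: list[SyntheticMuscleSpec], path) -> None:
    doc = []
    for s in specs:
        terms = []
        for t in s.terms:
            if isinstance(t, PulleyTerm):
                terms.append({"type": "pulley", "joint": t.joint,
                              "radius": t.radius, "sign": t.sign})
            else:
                terms.append({"type": "wrap", "joint": t.joint,
                              "amplitude": t.amplitude, "phase": t.phase})
        doc.append({"muscle": s.muscle_id, "base_length": s.base_length,
                    "terms": terms})
    with open(path, "w") as fh:
        yaml.safe_dump({"synthetic_limb": doc}, fh, sort_keys=False)


def specs_from_yaml(path) -> list[SyntheticMuscleSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = []
    for rec in doc["synthetic_limb"]:
        terms = []
        for t in rec["terms"]:
            if t["type"] == "pulley":
                terms.append(PulleyTerm(t["joint"], t["radius"],
                                        t.get("sign", 1)))
            elif t["type"] == "wrap":
                terms.append(WrapTerm(t["joint"], t["amplitude"],
                                      t.get("phase", 0.0)))
            else:
                raise ValueError(f"unknown term type {t['type']!r}")
        specs.append(SyntheticMuscleSpec(rec["muscle"], rec["base_length"],
                                         tuple(terms)))
    return specs
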