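"""End-to-end streaming loop: joint trajectory in, afferent firing rates out.

Per timestep the stages run in a fixed order, with previous-iteration state
feeding the estimates that would otherwise be circular:

1. evaluate the surrogate surfaces: musculotendon lengths and moment arms;
2. fiber length from the path length using the *previous* step's normalized
   force in the tendon-equilibrium cubic; fiber velocity by backward
   difference;
3. Hill curve coefficients -> per-muscle torque gains and passive torques;
4. activation-rate feasibility bounds from the previous activations;
5. min-max LP solve (with graceful slack relaxation), branch-sharing
   postprocess;
6. normalized force update, spindle (Ia, II) and GTO rates.

The loop is single-pass and causal (backward finite differences only), so
truncating the input to its first k samples reproduces the first k output
rows exactly, and identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .geometry import PolynomialSurface, fit_surface
from .gto import GtoModel, GtoParams
from .muscle import MuscleParams, force_coefficients
from .optimization import (activation_bounds, bootstrap_state, build_lp,
                           postprocess_branch_sharing, solve_min_max,
                           step_state, TAU_ACT, TAU_DEACT)
from .spindle import SpindleKinematics, SpindleModel
from .synthetic import (DEFAULT_BRANCH_GROUPS, SyntheticMuscleSpec,
                        Trajectory, generate_sample_table)

logger = logging.getLogger(__name__)

TORQUE_JOINTS = (4, 5, 6, 7)


@dataclass
class PipelineConfig:
    """Everything the streaming loop needs besides the trajectory itself."""

    muscles: list[MuscleParams]
    length_surfaces: dict[str, PolynomialSurface]
    ma_surfaces: dict[tuple[str, int], PolynomialSurface]
    torque_joints: tuple[int, ...] = TORQUE_JOINTS
    branch_groups: list = field(default_factory=lambda: list(DEFAULT_BRANCH_GROUPS))
    sum_weight: float = 0.01
    slack_penalty: float = 1e3
    tau_act: float = TAU_ACT
    tau_deact: float = TAU_DEACT
    spindle: SpindleModel = None
    gto: GtoParams = field(default_factory=GtoParams)
    gamma_static: float = 0.0
    gamma_dynamic: float = 0.0

    def __post_init__(self):
        if self.spindle is None:
            # human-rescaled gains by default; zero fusimotor drive
            self.spindle = SpindleModel().rescaled_human()
        names = [m.name for m in self.muscles]
        missing = [n for n in names if n not in self.length_surfaces]
        if missing:
            raise ValueError(f"no length surface for muscles {missing}")


def fit_surface_set(specs: list[SyntheticMuscleSpec], n_points: int = 11,
                    torque_joints=TORQUE_JOINTS):
    """Fit length and moment-arm surrogate surfaces for a synthetic roster."""
    lengths: dict[str, PolynomialSurface] = {}
    arms: dict[tuple[str, int], PolynomialSurface] = {}
    for spec in specs:
        table = generate_sample_table(spec, n_points, "length")
        lengths[spec.muscle_id] = fit_surface(table, spec.spanned_joints)
        for j in spec.spanned_joints:
            if j not in torque_joints:
                continue
            table = generate_sample_table(spec, n_points, "moment_arm", j)
            arms[(spec.muscle_id, j)] = fit_surface(table, spec.spanned_joints)
    return lengths, arms


def run_pipeline(trajectory: Trajectory, config: PipelineConfig) -> pd.DataFrame:
    """Run the full loop and return one output row per input sample."""
    n = len(trajectory)
    if n < 1:
        raise ValueError("empty trajectory")
    dt = trajectory.dt
    if n > 1 and dt <= 0:
        raise ValueError("trajectory must have a positive timestep")
    muscles = config.muscles
    m_count = len(muscles)
    names = [m.name for m in muscles]
    joints = tuple(config.torque_joints)
    j_count = len(joints)

    # per-muscle GTO filters designed at the trajectory rate
    fs = 1.0 / dt if dt > 0 else config.gto.fs
    gto_params = GtoParams(k1=config.gto.k1, k3=config.gto.k3,
                           num=config.gto.num, den=config.gto.den,
                           fs=fs, prewarp_hz=config.gto.prewarp_hz,
                           clamp=config.gto.clamp)
    gtos = [GtoModel(gto_params) for _ in muscles]

    # bootstrap: a=0, v=0, passive-force/tendon fixed point at the first pose
    states = []
    for m, params in enumerate(muscles):
        l_mt0 = config.length_surfaces[params.name](trajectory.q[0])
        st = bootstrap_state(l_mt0, params)
        states.append(st)
        gtos[m].reset(st.fm)

    lm_prev1 = np.array([s.lm for s in states])  # lengths at step i-1
    lm_prev2 = lm_prev1.copy()                   # lengths at step i-2

    excluded_logged = False
    rows = []
    for i in range(n):
        pose = trajectory.q[i]
        arms = np.zeros((m_count, j_count))
        lmt = np.zeros(m_count)
        for m, params in enumerate(muscles):
            lmt[m] = config.length_surfaces[params.name](pose)
            for k, j in enumerate(joints):
                surf = config.ma_surfaces.get((params.name, j))
                if surf is not None:
                    arms[m, k] = surf(pose)

        if i > 0:
            for m, params in enumerate(muscles):
                prev = states[m]
                lm = (lmt[m] - params.l_slack
                      * _tendon_len(prev.fm)) / params.l_opt
                # rigid-tendon velocity estimate (see optimization.step_state)
                vm = (lmt[m] - prev.lmt) / (dt * params.v_max)
                prev.lm, prev.vm, prev.lmt = lm, vm, lmt[m]
        else:
            for m in range(m_count):
                states[m].lmt = lmt[m]

        fl = np.zeros(m_count)
        fv = np.zeros(m_count)
        fp = np.zeros(m_count)
        for m, params in enumerate(muscles):
            fl[m], fv[m], fp[m] = force_coefficients(
                states[m].lm, states[m].vm, params)

        f_max = np.array([p.f_max for p in muscles])
        gains = (fl * fv * f_max)[:, None] * arms
        passive = (fp * f_max) @ arms

        a_prev = np.array([s.act for s in states])
        if i > 0:
            a_min, a_max = activation_bounds(a_prev, dt, config.tau_act,
                                             config.tau_deact)
        else:
            a_min, a_max = np.zeros(m_count), np.ones(m_count)

        # muscles with no torque authority about the resolved joints stay at
        # their lower bound and are excluded from the programme
        in_lp = np.abs(arms).max(axis=1) > 1e-12
        if not in_lp.all() and not excluded_logged:
            logger.info("muscles %s carry no moment about joints %s; held at "
                        "their lower activation bound",
                        [names[m] for m in np.flatnonzero(~in_lp)], joints)
            excluded_logged = True

        a = a_min.copy()
        if in_lp.any():
            problem = build_lp(gains[in_lp], passive, trajectory.tau[i],
                               a_min[in_lp], a_max[in_lp], config.sum_weight)
            result = solve_min_max(problem, config.slack_penalty)
            a[in_lp] = result.activations
        else:
            from .optimization import OptimizationResult
            residual = passive - trajectory.tau[i]
            result = OptimizationResult(
                a.copy(), float(a.max(initial=0.0)),
                "optimal" if np.abs(residual).max() < 1e-6 else "relaxed",
                -residual)
        a = postprocess_branch_sharing(a, gains, config.branch_groups, names)

        ia = np.zeros(m_count)
        ii = np.zeros(m_count)
        gto_rate = np.zeros(m_count)
        for m, params in enumerate(muscles):
            st = states[m]
            st.act = float(a[m])
            st.fm = st.act * fl[m] * fv[m] + fp[m]
            # causal spindle kinematics on the normalized-length series
            if i == 0:
                ld = ldd = 0.0
            else:
                ld = (st.lm - lm_prev1[m]) / dt
                ldd = ((st.lm - 2 * lm_prev1[m] + lm_prev2[m]) / dt ** 2
                       if i > 1 else 0.0)
            kin = SpindleKinematics(st.lm, ld, ldd)
            r = config.spindle.rates(kin, config.gamma_static,
                                     config.gamma_dynamic)
            ia[m], ii[m] = r.Ia, r.II
            gto_rate[m] = gtos[m].rate(st.fm)

        lm_prev2 = lm_prev1
        lm_prev1 = np.array([s.lm for s in states])

        row = {"time": trajectory.time[i], "beta": result.beta,
               "status": result.status}
        for k, j in enumerate(joints):
            row[f"residual{j}"] = result.torque_residual[k]
        for m, name in enumerate(names):
            row[f"act_{name}"] = a[m]
            row[f"lm_{name}"] = states[m].lm
            row[f"vm_{name}"] = states[m].vm
            row[f"fm_{name}"] = states[m].fm
            row[f"Ia_{name}"] = ia[m]
            row[f"II_{name}"] = ii[m]
            row[f"gto_{name}"] = gto_rate[m]
        rows.append(row)

    return pd.DataFrame(rows)


def _tendon_len(f_norm: float) -> float:
    # local alias keeps the hot loop free of array round-trips
    return ((0.04879 * f_norm - 0.1009) * f_norm + 0.1003) * f_norm + 1.0


# --- trajectory and output I/O --------------------------------------------

TRAJ_COLUMNS = (["time"] + [f"q{j}" for j in range(1, 8)]
                + [f"tau{j}" for j in TORQUE_JOINTS])


def read_trajectory(path, angles: str = "radians") -> Trajectory:
    """Strict CSV parse: header ``time,q1..q7,tau4..tau7``, uniform time.

    ``angles="degrees"`` converts the joint-angle columns by pi/180 on read.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(df.columns) != TRAJ_COLUMNS:
        raise ValueError(f"{path}: expected columns {TRAJ_COLUMNS}, "
                         f"got {list(df.columns)}")
    arr = df.to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(arr).all(axis=1))
    if bad.size:
        raise ValueError(f"{path}: non-finite value at data row {bad[0]}")
    t = arr[:, 0]
    if len(t) > 1:
        dts = np.diff(t)
        if np.any(dts <= 0):
            raise ValueError(f"{path}: non-monotone time at data row "
                             f"{int(np.flatnonzero(dts <= 0)[0]) + 1}")
        if np.any(np.abs(dts - dts[0]) > 1e-9 * max(1.0, abs(dts[0]))):
            row = int(np.flatnonzero(np.abs(dts - dts[0]) > 1e-9)[0]) + 1
            raise ValueError(f"{path}: non-uniform timestep at data row {row}")
    q = arr[:, 1:8]
    if angles == "degrees":
        q = q * (np.pi / 180.0)
    elif angles != "radians":
        raise ValueError(f"unknown angle unit {angles!r}")
    return Trajectory(t, q, arr[:, 8:12])


def write_trajectory(path, trajectory: Trajectory) -> None:
    data = np.column_stack([trajectory.time, trajectory.q, trajectory.tau])
    df = pd.DataFrame(data, columns=TRAJ_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def write_outputs(path, records: pd.DataFrame, config_meta: dict | None = None) -> None:
    """Write the output table with a metadata comment line (version + hash)."""
    meta = dict(config_meta or {})
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    digest = hashlib.sha256(blob).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(f"# propriosim={__version__} config_hash={digest}\n")
        records.to_csv(fh, index=False, float_format="%.17g")


def read_outputs(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
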