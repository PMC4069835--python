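"""Ensemble-average muscle-spindle firing (Ia and II afferents).

The spindle is modeled as three intrafusal fiber types (bag1, bag2, chain),
each a series arrangement of a compliant polar region (spring constant K_pr,
nonlinear velocity damping) and a stiff sensory region (spring constant
K_sr >> K_pr) whose stretch transduces into firing.  Because the sensory
region is much stiffer, essentially all imposed stretch is taken up by the
polar region; under that premise the fiber tension has a closed-form
equilibrium,

    T = M*Ldd + beta*C*(L - R - L_sr0)*|Ld|^0.3*sign(Ld)
        + K_pr*(L - L_pr0 - L_sr0) + Gamma,

with L the normalized muscle (fascicle) length in units of optimal length,
C the lengthening/shortening asymmetry, R the slack length below which the
damping term produces no force, and Gamma the steady-state intrafusal tension
from fusimotor drive.  Replacing the second-order tension ODE of the
anatomical model with this equilibrium removes the sub-millisecond step-size
requirement: the output is step-size independent, which is what allows the
spindle stage to run at the limb sample rate (e.g. 120 Hz).

Sensory-region stretch is T/K_sr + L_sr0; firing of each fiber is a gain G
times the stretch above a threshold.  The primary (Ia) afferent combines the
bag1 contribution with the summed bag2+chain contribution through partial
occlusion (larger + S * smaller); the secondary (II) afferent sums bag2 and
chain terms that mix sensory-region stretch with an X-weighted polar-region
term.  Gains fitted to feline data are divided by 15 to match the much lower
firing-rate changes observed in human microneurography.

The mechanical constants shipped here are cited-model defaults transcribed
from the intrafusal-fiber modeling literature; every property of this module
holds for any physically valid parameter set (K_sr >> K_pr > 0, C_L >= C_S > 0,
G >= 0), not just for these numbers.

A reference implementation that integrates the full second-order tension
dynamics by explicit Euler is included as an independent oracle: its fixed
point is the equilibrium expression above, it requires sub-millisecond steps
for stability, and it exhibits the transient (velocity-coupling and inertial)
effects the equilibrium model deliberately drops.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

VELOCITY_EXPONENT = 0.3  # |Ld|^0.3 damping nonlinearity
HUMAN_GAIN_FACTOR = 15.0  # feline-fitted gains divided by this for human rates


@dataclass(frozen=True)
class FiberParams:
    """Mechanical and sensory constants of one intrafusal fiber type.

    Lengths are in units of optimal fascicle length L0; tensions are in the
    cited model's normalized force units; gains G, G_II are pps per unit
    sensory-region stretch.
    """

    fiber_type: str            # "bag1" | "bag2" | "chain"
    M: float                   # mass term [force s^2 / L0]
    beta0: float               # baseline damping
    beta_gamma: float          # damping increment under full fusimotor drive
    c_len: float               # asymmetry coefficient, lengthening
    c_short: float             # asymmetry coefficient, shortening
    R: float                   # damping slack length [L0]
    k_sr: float                # sensory-region spring constant
    k_pr: float                # polar-region spring constant
    l_pr0: float               # polar rest length [L0]
    l_sr0: float               # sensory rest length [L0]
    l_sr_thresh: float         # sensory stretch threshold for firing [L0]
    G: float                   # primary firing gain [pps / L0]
    gamma_max: float = 0.0     # saturation tension of fusimotor drive
    gamma_half: float = 60.0   # fusimotor rate at half saturation [pps]
    gamma_p: float = 2.0       # fusimotor saturation exponent
    G_II: float = 0.0          # secondary firing gain (bag2/chain)
    X: float = 0.7             # secondary sensory/polar mixing fraction
    l_sec: float = 0.04        # secondary-ending length [L0]
    l_pr_thresh: float = 0.89  # polar stretch threshold for secondary term
    human_scaled: bool = False

    def __post_init__(self):
        if self.k_sr <= 0 or self.k_pr <= 0:
            raise ValueError("spring constants must be > 0")
        if self.k_sr <= self.k_pr:
            raise ValueError("sensory region must be stiffer than polar region")
        if not (self.c_len >= self.c_short > 0):
            raise ValueError("need C_L >= C_S > 0")
        if self.G < 0 or self.G_II < 0:
            raise ValueError("gains must be >= 0")


# Cited-model default constants (feline-fitted; see module docstring).
DEFAULT_BAG1 = FiberParams(
    fiber_type="bag1", M=0.0002, beta0=0.0605, beta_gamma=0.2592,
    c_len=1.0, c_short=0.42, R=0.46, k_sr=10.4649, k_pr=0.15,
    l_pr0=0.76, l_sr0=0.04, l_sr_thresh=0.0423, G=20000.0,
    gamma_max=0.0289, gamma_half=60.0)
DEFAULT_BAG2 = FiberParams(
    fiber_type="bag2", M=0.0002, beta0=0.0822, beta_gamma=0.046,
    c_len=1.0, c_short=0.42, R=0.46, k_sr=10.4649, k_pr=0.15,
    l_pr0=0.76, l_sr0=0.04, l_sr_thresh=0.0423, G=10000.0,
    gamma_max=0.0636, gamma_half=60.0, G_II=7250.0, X=0.7)
DEFAULT_CHAIN = FiberParams(
    fiber_type="chain", M=0.0002, beta0=0.0822, beta_gamma=0.069,
    c_len=1.0, c_short=0.42, R=0.46, k_sr=10.4649, k_pr=0.15,
    l_pr0=0.76, l_sr0=0.04, l_sr_thresh=0.0423, G=10000.0,
    gamma_max=0.0954, gamma_half=90.0, G_II=7250.0, X=0.7)

DEFAULT_OCCLUSION = 0.156  # partial-occlusion constant S


@dataclass
class SpindleKinematics:
    """Normalized fascicle length and its first two time derivatives."""

    L: float      # [L0]
    Ld: float     # [L0/s]
    Ldd: float    # [L0/s^2]


@dataclass
class AfferentRates:
    Ia: float  # [pps]
    II: float  # [pps]


def fusimotor_tension(gamma: float, fiber: FiberParams) -> float:
    """Steady-state intrafusal tension from a fusimotor rate [pps]."""
    if gamma < 0:
        raise ValueError("fusimotor rate must be >= 0")
    if gamma == 0:
        return 0.0
    g = gamma ** fiber.gamma_p
    return fiber.gamma_max * g / (g + fiber.gamma_half ** fiber.gamma_p)


def _beta(fiber: FiberParams, gamma: float) -> float:
    """Damping coefficient, raised under fusimotor drive (saturating)."""
    if gamma <= 0:
        return fiber.beta0
    return fiber.beta0 + fiber.beta_gamma * gamma / (gamma + fiber.gamma_half)


def _tension_rhs(L: float, Ld: float, Ldd: float, fiber: FiberParams,
                 gamma_tension: float, beta: float) -> float:
    """The equilibrium-tension expression (before the slack clamp)."""
    c = fiber.c_len if Ld > 0 else fiber.c_short
    damping = beta * c * (L - fiber.R - fiber.l_sr0) \
        * abs(Ld) ** VELOCITY_EXPONENT * np.sign(Ld)
    spring = fiber.k_pr * (L - fiber.l_pr0 - fiber.l_sr0)
    return fiber.M * Ldd + damping + spring + gamma_tension


def fiber_equilibrium_tension(kin: SpindleKinematics, fiber: FiberParams,
                              gamma_tension: float = 0.0,
                              gamma_rate: float = 0.0) -> float:
    """Equilibrium fiber tension; clamped at zero below slack."""
    t = _tension_rhs(kin.L, kin.Ld, kin.Ldd, fiber, gamma_tension,
                     _beta(fiber, gamma_rate))
    return max(0.0, t)


def fiber_firing_contribution(tension: float, fiber: FiberParams) -> float:
    """Primary-ending firing of one fiber from its tension [pps]."""
    if tension < 0:
        raise ValueError("fiber tension must be >= 0")
    stretch = tension / fiber.k_sr + fiber.l_sr0
    return fiber.G * max(0.0, stretch - fiber.l_sr_thresh)


def fiber_secondary_contribution(tension: float, L: float,
                                 fiber: FiberParams) -> float:
    """Secondary-ending firing term (bag2/chain only) [pps].

    Mixes sensory-region stretch (weight X) with the polar-region stretch the
    secondary ending also samples (weight 1-X), each above its threshold.
    """
    if fiber.G_II == 0:
        return 0.0
    s_sr = tension / fiber.k_sr + fiber.l_sr0
    sensory = (fiber.l_sec / fiber.l_sr0) * max(0.0, s_sr - fiber.l_sr_thresh)
    polar_len = L - (s_sr - fiber.l_sr0) - fiber.l_sr0
    polar = (fiber.l_sec / fiber.l_pr0) * max(0.0, polar_len - fiber.l_pr_thresh)
    return fiber.G_II * (fiber.X * sensory + (1.0 - fiber.X) * polar)


def combine_afferents(bag1_c: float, bag2_c: float, chain_c: float,
                      occlusion: float = DEFAULT_OCCLUSION,
                      ii_terms: tuple[float, float] = (0.0, 0.0)) -> AfferentRates:
    """Non-linear summation of the fiber contributions into Ia and II rates.

    The two primary components are bag1 and (bag2 + chain); partial occlusion
    passes the larger in full and the smaller scaled by S in [0, 1].
    """
    for v in (bag1_c, bag2_c, chain_c):
        if v < 0:
            raise ValueError("fiber contributions must be >= 0")
    p1 = bag1_c
    p2 = bag2_c + chain_c
    ia = max(p1, p2) + occlusion * min(p1, p2)
    ii = max(0.0, ii_terms[0]) + max(0.0, ii_terms[1])
    return AfferentRates(Ia=ia, II=ii)


def rescale_gain_human(fiber: FiberParams,
                       factor: float = HUMAN_GAIN_FACTOR) -> FiberParams:
    """Divide the feline-fitted firing gains by ``factor`` (once).

    Fusimotor stimulation changes feline spindle rates by up to ~150 pps but
    human rates by < 30 pps, hence the division.  A guard flag prevents
    accidental double application.
    """
    if fiber.human_scaled:
        raise ValueError("gains already rescaled to human range")
    return replace(fiber, G=fiber.G / factor, G_II=fiber.G_II / factor,
                   human_scaled=True)


def calibrate_rest_lengths(fiber: FiberParams,
                           l_neutral: float) -> FiberParams:
    """Shift rest/slack lengths so the fiber is at rest at ``l_neutral``.

    For muscles physiologically constrained away from their optimal length
    the default rest length (near L=0.8) would make the spindle fire across
    the whole range of motion; this translates the polar rest length and the
    damping slack length so that static tension (and firing, given zero
    fusimotor drive) is zero at the neutral pose, while the response to
    stretch *relative to neutral* is unchanged (a pure translation).
    """
    if l_neutral <= 0:
        raise ValueError("neutral length must be > 0")
    delta = l_neutral - (fiber.l_pr0 + fiber.l_sr0)
    return replace(fiber, l_pr0=fiber.l_pr0 + delta, R=fiber.R + delta,
                   l_pr_thresh=fiber.l_pr_thresh + delta)


@dataclass
class SpindleModel:
    """One muscle's spindle ensemble: three fiber types plus occlusion."""

    bag1: FiberParams = DEFAULT_BAG1
    bag2: FiberParams = DEFAULT_BAG2
    chain: FiberParams = DEFAULT_CHAIN
    occlusion: float = DEFAULT_OCCLUSION

    def rescaled_human(self) -> "SpindleModel":
        return SpindleModel(rescale_gain_human(self.bag1),
                            rescale_gain_human(self.bag2),
                            rescale_gain_human(self.chain), self.occlusion)

    def calibrated(self, l_neutral: float) -> "SpindleModel":
        return SpindleModel(calibrate_rest_lengths(self.bag1, l_neutral),
                            calibrate_rest_lengths(self.bag2, l_neutral),
                            calibrate_rest_lengths(self.chain, l_neutral),
                            self.occlusion)

    def rates(self, kin: SpindleKinematics, gamma_static: float = 0.0,
              gamma_dynamic: float = 0.0) -> AfferentRates:
        """Ia/II rates at one sample.  Dynamic drive tensions bag1; static
        drive tensions bag2 and chain (standard fusimotor routing)."""
        t1 = fiber_equilibrium_tension(
            kin, self.bag1, fusimotor_tension(gamma_dynamic, self.bag1),
            gamma_dynamic)
        t2 = fiber_equilibrium_tension(
            kin, self.bag2, fusimotor_tension(gamma_static, self.bag2),
            gamma_static)
        tc = fiber_equilibrium_tension(
            kin, self.chain, fusimotor_tension(gamma_static, self.chain),
            gamma_static)
        ii = (fiber_secondary_contribution(t2, kin.L, self.bag2),
              fiber_secondary_contribution(tc, kin.L, self.chain))
        return combine_afferents(
            fiber_firing_contribution(t1, self.bag1),
            fiber_firing_contribution(t2, self.bag2),
            fiber_firing_contribution(tc, self.chain),
            self.occlusion, ii)

    def rates_series(self, lengths, dt: float, gamma_static: float = 0.0,
                     gamma_dynamic: float = 0.0,
                     scheme: str = "central") -> tuple[np.ndarray, np.ndarray]:
        """Ia/II series for a normalized-length trajectory sampled at dt."""
        kins = kinematics_from_lengths(lengths, dt, scheme)
        ia = np.empty(len(kins))
        ii = np.empty(len(kins))
        for i, kin in enumerate(kins):
            r = self.rates(kin, gamma_static, gamma_dynamic)
            ia[i], ii[i] = r.Ia, r.II
        return ia, ii


def kinematics_from_lengths(lengths, dt: float,
                            scheme: str = "central") -> list[SpindleKinematics]:
    """Differentiate a sampled length trajectory into spindle kinematics.

    ``scheme="central"`` uses second-order central differences (one-sided at
    the endpoints) and suits offline trajectories; ``scheme="backward"`` is
    strictly causal for streaming use.
    """
    L = np.asarray(lengths, dtype=float)
    if L.ndim != 1 or len(L) < 1:
        raise ValueError("lengths must be a 1-D series")
    n = len(L)
    if n == 1:
        return [SpindleKinematics(float(L[0]), 0.0, 0.0)]
    if scheme == "central":
        Ld = np.gradient(L, dt)
        Ldd = np.gradient(Ld, dt)
    elif scheme == "backward":
        Ld = np.zeros(n)
        Ld[1:] = np.diff(L) / dt
        Ldd = np.zeros(n)
        if n > 2:
            Ldd[2:] = (L[2:] - 2 * L[1:-1] + L[:-2]) / dt ** 2
    else:
        raise ValueError(f"unknown differencing scheme {scheme!r}")
    return [SpindleKinematics(float(L[i]), float(Ld[i]), float(Ldd[i]))
            for i in range(n)]


# --- full-ODE Euler reference (independent oracle) -------------------------

class OdeInstabilityError(RuntimeError):
    """Euler integration of the tension dynamics diverged; reduce dt_inner."""


def reference_fiber_tension_ode(lengths, dt: float, fiber: FiberParams,
                                gamma_tension: float = 0.0,
                                gamma_rate: float = 0.0,
                                dt_inner: float | None = None,
                                tension0: float | None = None) -> np.ndarray:
    """Integrate the un-approximated second-order tension dynamics by Euler.

    The dynamic model retains what the equilibrium expression drops: the
    fiber mass and the coupling of the sensory-region end's own motion
    (Td/K_sr) into the polar-region velocity,

        (M / K_sr) * Tdd = T_eq(L, Ld - Td/K_sr, Ldd) - T,

    whose fixed point at constant length is exactly the equilibrium tension.
    Explicit Euler on this stiff oscillator needs steps of order 0.1-1 ms;
    divergence is detected and reported rather than silently returned.

    The integration starts from the rest state at the first sample unless
    ``tension0`` overrides the initial tension (perturbation studies).
    Returns the tension at the input samples (clamped at zero like the
    equilibrium output).
    """
    L = np.asarray(lengths, dtype=float)
    if dt_inner is None:
        dt_inner = dt
    n_sub = max(1, int(round(dt / dt_inner)))
    h = dt / n_sub
    beta = _beta(fiber, gamma_rate)

    kins = kinematics_from_lengths(L, dt, scheme="central")
    Ld = np.array([k.Ld for k in kins])
    Ldd = np.array([k.Ldd for k in kins])

    omega2 = fiber.k_sr / fiber.M
    t = (_tension_rhs(L[0], 0.0, 0.0, fiber, gamma_tension, beta)
         if tension0 is None else float(tension0))
    td = 0.0
    out = np.empty(len(L))
    out[0] = max(0.0, t)
    limit = 1e4 * (1.0 + abs(t))
    for i in range(1, len(L)):
        # linear interpolation of the kinematic inputs across the sample
        for s in range(n_sub):
            frac = s / n_sub
            Li = L[i - 1] + frac * (L[i] - L[i - 1])
            Ldi = Ld[i - 1] + frac * (Ld[i] - Ld[i - 1])
            Lddi = Ldd[i - 1] + frac * (Ldd[i] - Ldd[i - 1])
            v_polar = Ldi - td / fiber.k_sr
            target = _tension_rhs(Li, v_polar, Lddi, fiber, gamma_tension, beta)
            tdd = omega2 * (target - t)
            t += h * td
            td += h * tdd
            if not np.isfinite(t) or abs(t) > limit:
                raise OdeInstabilityError(
                    f"{fiber.fiber_type} tension diverged at sample {i} "
                    f"(dt_inner={h:.2e} s); use a smaller inner step")
        out[i] = max(0.0, t)
    return out


def reference_rates_series(model: SpindleModel, lengths, dt: float,
                           gamma_static: float = 0.0,
                           gamma_dynamic: float = 0.0,
                           dt_inner: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Ia/II series from the Euler reference solver (oracle pipeline)."""
    L = np.asarray(lengths, dtype=float)
    t1 = reference_fiber_tension_ode(
        L, dt, model.bag1, fusimotor_tension(gamma_dynamic, model.bag1),
        gamma_dynamic, dt_inner)
    t2 = reference_fiber_tension_ode(
        L, dt, model.bag2, fusimotor_tension(gamma_static, model.bag2),
        gamma_static, dt_inner)
    tc = reference_fiber_tension_ode(
        L, dt, model.chain, fusimotor_tension(gamma_static, model.chain),
        gamma_static, dt_inner)
    ia = np.empty(len(L))
    ii = np.empty(len(L))
    for i in range(len(L)):
        r = combine_afferents(
            fiber_firing_contribution(t1[i], model.bag1),
            fiber_firing_contribution(t2[i], model.bag2),
            fiber_firing_contribution(tc[i], model.chain),
            model.occlusion,
            (fiber_secondary_contribution(t2[i], L[i], model.bag2),
             fiber_secondary_contribution(tc[i], L[i], model.chain)))
        ia[i], ii[i] = r.Ia, r.II
    return ia, ii


# --- config I/O ------------------------------------------------------------

_FIBER_FIELDS = [f for f in FiberParams.__dataclass_fields__]


def spindle_to_yaml(model: SpindleModel, path) -> None:
    doc = {
        "occlusion": float(model.occlusion),
        "human_scaling": False,
        "fibers": {
            f.fiber_type: {k: getattr(f, k) for k in _FIBER_FIELDS
                           if k != "fiber_type"}
            for f in (model.bag1, model.bag2, model.chain)
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spindle_from_yaml(path) -> SpindleModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    fibers = {}
    for name in ("bag1", "bag2", "chain"):
        rec = dict(doc["fibers"][name])
        fibers[name] = FiberParams(fiber_type=name, **rec)
    model = SpindleModel(fibers["bag1"], fibers["bag2"], fibers["chain"],
                         doc.get("occlusion", DEFAULT_OCCLUSION))
    if doc.get("human_scaling", False):
        model = model.rescaled_human()
    return model
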