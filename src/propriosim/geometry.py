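"""Polynomial surrogate geometry: joint angles -> musculotendon length / moment arm.

Running a full 3D musculoskeletal path model (origin/insertion points plus
wrapping surfaces) is far too slow for a real-time afferent simulator.  Instead,
each muscle's musculotendon length L^MT(q) and each of its moment arms
R_mj(q) are approximated by sparse cubic polynomial surfaces over the joint
angles the muscle spans,

    L^MT_m(q) = sum_i c_i * prod_j q_j**e_ij,      e_ij in {0..3},

fitted by ordinary least squares to tables of (pose, value) samples swept over
the joints' ranges of motion.  The surfaces evaluate in a handful of multiply-
adds per muscle, which is what makes the downstream pipeline real-time.

Sign convention: the moment arm of muscle m about joint j equals the negative
partial derivative of musculotendon length with respect to q_j (tendon
excursion), so a muscle that shortens as q_j increases has a positive moment
arm and produces positive torque about j.
"""

from __future__ import annotations

import csv
import io
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

N_JOINTS = 7

#: 1-based joint numbering used throughout: 1-3 shoulder (elevation-plane
#: angle, elevation, rotation), 4 elbow flexion, 5 forearm pronation,
#: 6 wrist flexion, 7 wrist deviation.
JOINT_NAMES = (
    "shoulder_plane",
    "shoulder_elevation",
    "shoulder_rotation",
    "elbow_flexion",
    "forearm_pronation",
    "wrist_flexion",
    "wrist_deviation",
)

#: Default joint ranges of motion [rad], (lo, hi) per joint, 1-based order.
DEFAULT_JOINT_RANGES = np.array(
    [
        (-1.2, 2.0),   # shoulder elevation-plane angle
        (0.0, 3.0),    # shoulder elevation
        (-1.5, 1.5),   # shoulder rotation
        (0.0, 2.27),   # elbow flexion
        (-1.5, 1.5),   # forearm pronation
        (-1.2, 1.2),   # wrist flexion
        (-0.44, 0.61), # wrist deviation (radial-/ulnar+)
    ]
)


class FitError(ValueError):
    """Raised when a surface cannot be fitted (rank deficiency, too few rows)."""


def as_pose(q) -> np.ndarray:
    """Validate and return a 7-vector joint pose [rad]."""
    q = np.asarray(q, dtype=float)
    if q.shape != (N_JOINTS,):
        raise ValueError(f"pose must be a 7-vector, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("pose contains non-finite angles")
    return q


@dataclass
class SampleTable:
    """Table of (pose, value) samples for one muscle and one target quantity.

    ``poses`` is (n, 7) [rad]; ``values`` is (n,) [m].
    """

    poses: np.ndarray
    values: np.ndarray
    muscle: str = ""
    target: str = "length"
    joint_index: int | None = None  # 1-based, moment-arm tables only

    def __post_init__(self):
        self.poses = np.atleast_2d(np.asarray(self.poses, dtype=float))
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.poses.shape[1] != N_JOINTS:
            raise ValueError("poses must have 7 columns")
        if self.poses.shape[0] != self.values.shape[0]:
            raise ValueError("poses and values row counts differ")

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([f"q{j}" for j in range(1, 8)] + ["value"])
            for pose, val in zip(self.poses, self.values):
                w.writerow([repr(float(x)) for x in pose] + [repr(float(val))])

    @classmethod
    def from_csv(cls, path, muscle: str = "", target: str = "length",
                 joint_index: int | None = None) -> "SampleTable":
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            header = next(r)
            expected = [f"q{j}" for j in range(1, 8)] + ["value"]
            if [h.strip() for h in header] != expected:
                raise ValueError(f"bad sample-table header {header!r}")
            rows = [[float(x) for x in row] for row in r if row]
        arr = np.asarray(rows, dtype=float)
        return cls(arr[:, :7], arr[:, 7], muscle=muscle, target=target,
                   joint_index=joint_index)


@dataclass
class PolynomialSurface:
    """Sparse multivariate polynomial mapping a joint pose to a scalar [m].

    ``coeffs`` is (n_terms,) and ``exponents`` is (n_terms, 7) of ints in
    [0, 3]; each term's total degree is at most the fit degree (3 by default).
    """

    coeffs: np.ndarray
    exponents: np.ndarray
    muscle: str = ""
    target: str = "length"          # "length" | "moment_arm"
    joint_index: int | None = None  # 1-based; moment-arm surfaces only
    fitted_range: np.ndarray | None = field(default=None, repr=False)
    _range_warned: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float).ravel()
        self.exponents = np.atleast_2d(np.asarray(self.exponents, dtype=int))
        if self.exponents.shape != (len(self.coeffs), N_JOINTS):
            raise ValueError("exponents must be (n_terms, 7)")
        if len(self.coeffs) == 0:
            raise ValueError("surface needs at least one term")
        if self.exponents.min() < 0 or self.exponents.max() > 3:
            raise ValueError("exponents must lie in [0, 3]")

    @property
    def spanned_joints(self) -> tuple[int, ...]:
        """1-based joints with any nonzero exponent."""
        mask = (self.exponents != 0).any(axis=0)
        return tuple(int(j) + 1 for j in np.flatnonzero(mask))

    def __call__(self, pose) -> float:
        pose = as_pose(pose)
        if self.fitted_range is not None and not self._range_warned:
            # only the spanned joints constrain the fit; others are inert
            idx = [j - 1 for j in self.spanned_joints]
            lo = self.fitted_range[idx, 0]
            hi = self.fitted_range[idx, 1]
            if np.any(pose[idx] < lo - 1e-12) or np.any(pose[idx] > hi + 1e-12):
                logger.warning(
                    "evaluating surface %s/%s outside its fitted range "
                    "(reported once)", self.muscle, self.target)
                self._range_warned = True
        return float(np.dot(self.coeffs,
                            np.prod(pose[None, :] ** self.exponents, axis=1)))

    def evaluate_many(self, poses: np.ndarray) -> np.ndarray:
        """Vectorized evaluation at an (n, 7) block of poses."""
        poses = np.atleast_2d(np.asarray(poses, dtype=float))
        # (n, terms, 7) power table collapses to the design matrix
        mono = np.prod(poses[:, None, :] ** self.exponents[None, :, :], axis=2)
        return mono @ self.coeffs

    def gradient(self, pose) -> np.ndarray:
        """Exact analytic gradient d(value)/dq, a 7-vector [m/rad]."""
        pose = as_pose(pose)
        grad = np.zeros(N_JOINTS)
        for j in range(N_JOINTS):
            e = self.exponents[:, j]
            active = e > 0
            if not active.any():
                continue
            ed = self.exponents[active].copy()
            ed[:, j] -= 1
            mono = np.prod(pose[None, :] ** ed, axis=1)
            grad[j] = np.dot(self.coeffs[active] * e[active], mono)
        return grad

    # --- JSON persistence (bit-stable at 17 significant digits) ---

    def to_dict(self) -> dict:
        d = {
            "muscle": self.muscle,
            "target": self.target,
            "terms": [
                {"coeff": float(c), "exponents": [int(e) for e in row]}
                for c, row in zip(self.coeffs, self.exponents)
            ],
        }
        if self.joint_index is not None:
            d["joint_index"] = int(self.joint_index)
        if self.fitted_range is not None:
            d["fitted_range"] = self.fitted_range.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialSurface":
        return cls(
            coeffs=[t["coeff"] for t in d["terms"]],
            exponents=[t["exponents"] for t in d["terms"]],
            muscle=d.get("muscle", ""),
            target=d.get("target", "length"),
            joint_index=d.get("joint_index"),
            fitted_range=(np.asarray(d["fitted_range"])
                          if "fitted_range" in d else None),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "PolynomialSurface":
        return cls.from_dict(json.loads(Path(path).read_text()))


def term_basis(spanned_joints, degree: int = 3) -> np.ndarray:
    """All monomial exponent rows over ``spanned_joints`` (1-based).

    Per-variable exponent <= min(degree, 3) and total degree <= degree.
    Returns an (n_terms, 7) int array including the constant term.
    """
    spanned = sorted(set(int(j) for j in spanned_joints))
    if any(j < 1 or j > N_JOINTS for j in spanned):
        raise ValueError("spanned joints must be 1-based indices in 1..7")
    per_var = min(degree, 3)
    rows = []
    for combo in itertools.product(range(per_var + 1), repeat=len(spanned)):
        if sum(combo) > degree:
            continue
        row = np.zeros(N_JOINTS, dtype=int)
        for j, e in zip(spanned, combo):
            row[j - 1] = e
        rows.append(row)
    rows.sort(key=lambda r: (int(r.sum()), r.tolist()))
    return np.asarray(rows, dtype=int)


def design_matrix(poses: np.ndarray, exponents: np.ndarray) -> np.ndarray:
    poses = np.atleast_2d(np.asarray(poses, dtype=float))
    return np.prod(poses[:, None, :] ** exponents[None, :, :], axis=2)


def fit_surface(samples: SampleTable, spanned_joints=None,
                degree: int = 3) -> PolynomialSurface:
    """Least-squares fit of a cubic polynomial surface to a sample table.

    ``spanned_joints`` (1-based) restricts the monomial basis to the joints
    the muscle actually spans; by default every joint whose angle varies in
    the table is considered spanned.
    """
    if spanned_joints is None:
        varies = np.ptp(samples.poses, axis=0) > 1e-12
        spanned_joints = tuple(int(j) + 1 for j in np.flatnonzero(varies))
        if not spanned_joints:
            spanned_joints = (1,)
    exponents = term_basis(spanned_joints, degree)
    if len(samples) < len(exponents):
        raise FitError(
            f"muscle {samples.muscle!r}: {len(samples)} rows < "
            f"{len(exponents)} polynomial terms")
    A = design_matrix(samples.poses, exponents)
    coeffs, _, rank, _ = np.linalg.lstsq(A, samples.values, rcond=None)
    if rank < len(exponents):
        logger.warning(
            "muscle %r: rank-deficient design matrix (rank %d < %d terms); "
            "minimum-norm solution used", samples.muscle, rank, len(exponents))
        col_span = np.ptp(A, axis=0) > 0
        if not np.all(col_span | (exponents.sum(axis=1) == 0)):
            raise FitError(
                f"muscle {samples.muscle!r}: degenerate sample table "
                "(some basis monomials are constant over the samples)")
    rng = np.column_stack([samples.poses.min(axis=0), samples.poses.max(axis=0)])
    return PolynomialSurface(coeffs, exponents, muscle=samples.muscle,
                             target=samples.target,
                             joint_index=samples.joint_index,
                             fitted_range=rng)


def goodness_of_fit(surface: PolynomialSurface, samples: SampleTable) -> float:
    """Coefficient of determination R^2 = 1 - SS_res/SS_tot."""
    pred = surface.evaluate_many(samples.poses)
    resid = samples.values - pred
    ss_tot = float(np.sum((samples.values - samples.values.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: samples have zero variance")
    return 1.0 - float(np.sum(resid ** 2)) / ss_tot


def evaluate_surface(surface: PolynomialSurface, pose) -> float:
    """Functional alias for ``surface(pose)``."""
    return surface(pose)


def surface_gradient(surface: PolynomialSurface, pose) -> np.ndarray:
    """Functional alias for ``surface.gradient(pose)``."""
    return surface.gradient(pose)
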