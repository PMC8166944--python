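"""Segment and joint kinematics.

Orientation bookkeeping for the pipeline: XYZ Cardan angles (intrinsic,
body-fixed axes), unit quaternions for composing relative joint rotations,
zero-phase low-pass filtering of kinematic/kinetic channels, numerical
differentiation, and normalization of time series to the gait cycle.

Conventions
-----------
* Cardan sequence is intrinsic XYZ: ``R = Rx(rx) @ Ry(ry) @ Rz(rz)``.
  About the local x axis is protraction/retraction (flexion/extension),
  y abduction/adduction, z axial rotation.
* Quaternions are scalar-first ``(w, x, y, z)``, canonicalized to ``w >= 0``.
* Relative joint rotation between an upper (proximal) and lower (distal)
  segment is ``q_lower* ⊗ q_upper``, i.e. the rotation of the upper segment
  expressed in the lower segment's frame, then decomposed back to XYZ
  Cardan angles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

__all__ = [
    "CardanAngles",
    "Quaternion",
    "PoseSeries",
    "GaitEvents",
    "rot_x",
    "rot_y",
    "rot_z",
    "cardan_matrix",
    "matrix_to_cardan",
    "cardan_to_quaternion",
    "quaternion_to_cardan",
    "relative_joint_angles",
    "enforce_quaternion_continuity",
    "lowpass",
    "differentiate",
    "normalize_gait",
]

#: |ry| this close to pi/2 is flagged as gimbal-lock proximity.
GIMBAL_TOL = 1e-6


@dataclass(frozen=True)
class CardanAngles:
    """Intrinsic XYZ Cardan angles in radians."""

    rx: float
    ry: float
    rz: float
    gimbal_warning: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz])


@dataclass(frozen=True)
class Quaternion:
    """Unit quaternion, scalar first, canonical sign ``w >= 0``."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self):
        n = np.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"quaternion norm {n} not within 1e-9 of 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])

    def conjugate(self) -> "Quaternion":
        return _canonical(self.w, -self.x, -self.y, -self.z)

    def __matmul__(self, other: "Quaternion") -> "Quaternion":
        """Hamilton product; composes rotations like matrix product."""
        w1, x1, y1, z1 = self.as_array()
        w2, x2, y2, z2 = other.as_array()
        return _canonical(
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        )

    def as_matrix(self) -> np.ndarray:
        return Rotation.from_quat(
            [self.x, self.y, self.z, self.w]
        ).as_matrix()


def _canonical(w, x, y, z) -> Quaternion:
    v = np.array([w, x, y, z], dtype=float)
    v /= np.linalg.norm(v)
    if v[0] < 0 or (v[0] == 0 and (v[np.nonzero(v)[0][0]] < 0 if np.any(v) else False)):
        v = -v
    return Quaternion(*v)


def rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def cardan_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix of the intrinsic XYZ sequence, ``Rx @ Ry @ Rz``."""
    return rot_x(rx) @ rot_y(ry) @ rot_z(rz)


def matrix_to_cardan(R: np.ndarray) -> CardanAngles:
    """Decompose a rotation matrix into intrinsic XYZ Cardan angles."""
    rx, ry, rz = Rotation.from_matrix(R).as_euler("XYZ")
    return CardanAngles(rx, ry, rz, gimbal_warning=abs(abs(ry) - np.pi / 2) < GIMBAL_TOL)


def cardan_to_quaternion(angles: CardanAngles) -> Quaternion:
    """Unit quaternion of the rotation ``Rx(rx) @ Ry(ry) @ Rz(rz)``."""
    x, y, z, w = Rotation.from_euler(
        "XYZ", [angles.rx, angles.ry, angles.rz]
    ).as_quat()
    return _canonical(w, x, y, z)


def quaternion_to_cardan(q: Quaternion) -> CardanAngles:
    """Intrinsic XYZ Cardan angles of a unit quaternion.

    Flags gimbal-lock proximity (|ry| within ``GIMBAL_TOL`` of pi/2) on the
    returned angles instead of raising.
    """
    r = Rotation.from_quat([q.x, q.y, q.z, q.w])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at exact gimbal lock
        rx, ry, rz = r.as_euler("XYZ")
    return CardanAngles(rx, ry, rz, gimbal_warning=abs(abs(ry) - np.pi / 2) < GIMBAL_TOL)


def relative_joint_angles(q_upper: Quaternion, q_lower: Quaternion) -> CardanAngles:
    """Relative joint rotation between adjacent segments as Cardan angles.

    The lower (distal) segment quaternion is conjugated and multiplied by the
    upper (proximal) segment quaternion; the product is decomposed into
    intrinsic XYZ Cardan angles.  Equivalent to decomposing
    ``R_lower.T @ R_upper``.
    """
    return quaternion_to_cardan(q_lower.conjugate() @ q_upper)


def enforce_quaternion_continuity(qs: list[Quaternion]) -> list[Quaternion]:
    """Resolve the q/-q sign ambiguity along a time series.

    Keeps nearest-neighbour continuity (dot product with the previous sample
    non-negative), overriding the per-sample ``w >= 0`` canonical sign.
    """
    if not qs:
        return []
    out = [qs[0]]
    for q in qs[1:]:
        v = q.as_array()
        if float(out[-1].as_array() @ v) < 0:
            v = -v
        out.append(Quaternion(*v))
    return out


def lowpass(series: np.ndarray, cutoff_hz: float, rate_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    The conventional gait-analysis filter: an ``order``-th Butterworth design
    applied forward and backward (``filtfilt``), so the passband is preserved
    without phase lag.  Default cutoff used throughout the pipeline is 6 Hz
    for both kinematic and ground-reaction-force channels.

    Parameters
    ----------
    series:
        Samples, shape ``(n,)`` or ``(n, k)`` (filtered along axis 0).
    cutoff_hz, rate_hz:
        Cutoff and sampling rate; requires ``rate_hz > 2 * cutoff_hz``.
    """
    series = np.asarray(series, dtype=float)
    if not rate_hz > 2 * cutoff_hz:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {rate_hz / 2} Hz"
        )
    b, a = butter(order, cutoff_hz / (rate_hz / 2))
    return filtfilt(b, a, series, axis=0)


def differentiate(series: np.ndarray, time: np.ndarray, order: int = 1) -> np.ndarray:
    """Finite-difference derivative on a uniform time grid.

    Central differences at interior samples, second-order one-sided stencils
    at the boundaries (exact for polynomials up to quadratic).  ``order`` may
    be 1 or 2; order 2 applies the scheme twice.
    """
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    if time.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise ValueError("time grid must be uniform")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    d = np.gradient(series, time[1] - time[0], axis=0, edge_order=2)
    if order == 2:
        d = np.gradient(d, time[1] - time[0], axis=0, edge_order=2)
    return d


@dataclass(frozen=True)
class GaitEvents:
    """Sample indices of touchdown and toe-off within a trial."""

    touchdown: int
    toeoff: int
    next_touchdown: int

    def __post_init__(self):
        if not self.touchdown < self.toeoff < self.next_touchdown:
            raise ValueError(
                "gait events must be ordered touchdown < toeoff < next touchdown"
            )


def normalize_gait(
    series: np.ndarray,
    time: np.ndarray,
    events: GaitEvents,
    n_points: int = 101,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Resample one stride (touchdown to touchdown) to a 0-100% grid.

    Returns ``(percent_grid, resampled, stance_fraction)`` where the stance
    fraction locates the stance/swing boundary (toe-off) on the grid.
    """
    series = np.asarray(series, dtype=float)
    t0, t1 = time[events.touchdown], time[events.next_touchdown]
    t_off = time[events.toeoff]
    percent = np.linspace(0.0, 100.0, n_points)
    t_query = t0 + (percent / 100.0) * (t1 - t0)
    if series.ndim == 1:
        resampled = np.interp(t_query, time, series)
    else:
        resampled = np.column_stack(
            [np.interp(t_query, time, series[:, j]) for j in range(series.shape[1])]
        )
    stance_fraction = float((t_off - t0) / (t1 - t0))
    return percent, resampled, stance_fraction


@dataclass
class PoseSeries:
    """Generalized coordinates for all joints over time.

    ``q``, ``qd``, ``qdd`` map joint name to an ``(n, 6)`` array in the DOF
    order ``(rx, ry, rz, tx, ty, tz)`` (radians / metres); disabled DOFs hold
    zeros.  Derivatives may be supplied analytically (synthetic fixtures) or
    produced by :func:`differentiate`.
    """

    time: np.ndarray
    q: dict[str, np.ndarray]
    qd: dict[str, np.ndarray] = field(default_factory=dict)
    qdd: dict[str, np.ndarray] = field(default_factory=dict)
    events: GaitEvents | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be a strictly increasing 1-D grid")
        n = self.time.size
        for name, arr in self.q.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 6):
                raise ValueError(f"q[{name!r}] must have shape ({n}, 6)")
            self.q[name] = arr
        if self.events is not None and not (
            0 <= self.events.touchdown and self.events.next_touchdown < n
        ):
            raise ValueError("gait events outside the time range")

    @property
    def n_samples(self) -> int:
        return self.time.size

    def fill_derivatives(self) -> "PoseSeries":
        """Populate qd/qdd by finite differences where missing."""
        for name, arr in self.q.items():
            if name not in self.qd:
                self.qd[name] = differentiate(arr, self.time, order=1)
            if name not in self.qdd:
                self.qdd[name] = differentiate(self.qd[name], self.time, order=1)
        return self

    def frame(self, i: int) -> tuple[dict, dict, dict]:
        """(q, qd, qdd) dicts of (6,) vectors at sample ``i``."""
        q = {k: v[i] for k, v in self.q.items()}
        qd = {k: self.qd[k][i] if k in self.qd else np.zeros(6) for k in self.q}
        qdd = {k: self.qdd[k][i] if k in self.qdd else np.zeros(6) for k in self.q}
        return q, qd, qdd
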