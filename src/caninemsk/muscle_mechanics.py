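"""Muscle path geometry, moment arms, and Hill-type static force.

Muscle paths are polylines of attachment points on segments.  Where a
straight path segment would penetrate a wrap obstacle — a cylinder at a
hinge joint or a sphere at a ball-and-socket joint — the segment is
replaced by a tangent–arc–tangent construction, keeping the path outside
the obstacle and its length continuous in the pose.

Moment arms follow the tendon-excursion method: the arm of muscle *i*
about generalized coordinate *j* is the negative partial derivative of
musculotendon length with respect to that coordinate, approximated by
central differences.

The static muscle force is a rigid-tendon Hill model: the fibre carries an
active force-length contribution scaled linearly by activation plus a
passive elastic contribution, both multiplied by the maximum isometric
force and the pennation cosine.  Velocity scaling is deliberately omitted:
static optimization resolves torques frame by frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import ModelConfig, Muscle, MuscleParams, WrapObstacle

__all__ = [
    "PathState",
    "MomentArmMatrix",
    "estimate_tendon_length",
    "path_length",
    "moment_arms",
    "muscle_force",
    "active_force_length",
    "passive_force_length",
    "fibre_state",
]

#: Gaussian width of the active force-length curve (dimensionless fibre length).
FL_WIDTH = 0.45
#: Passive curve shape: zero at or below optimal length, reaching 1 at 1 + PASSIVE_STRAIN.
PASSIVE_STRAIN = 0.7
PASSIVE_SHAPE = 5.0


class GeometryError(ValueError):
    """Inadmissible muscle-path geometry (point inside an obstacle, …)."""


def estimate_tendon_length(ml: float, fl: float, alpha: float) -> float:
    """Tendon length from muscle length, fibre length, and pennation.

    ``tl = ml - fl * cos(alpha)``: the fibre's projection onto the
    muscle-tendon line of action is removed from the total length.  A
    fully fleshed muscle (fl == ml, alpha == 0) has zero tendon.  Negative
    results (possible with noisy morphometry) are clipped to zero with a
    warning.
    """
    if not 0 <= alpha < np.pi / 2:
        raise ValueError("pennation angle must lie in [0, pi/2)")
    if fl > ml:
        warnings.warn("fibre length exceeds muscle length; check morphometry")
    tl = ml - fl * np.cos(alpha)
    if tl < 0:
        warnings.warn("estimated tendon length negative; clipping to 0")
        return 0.0
    return float(tl)


# ---------------------------------------------------------------------------
# wrapping geometry


def _wrap_2d(p1: np.ndarray, p2: np.ndarray, r: float):
    """Planar tangent-arc-tangent wrap of the segment p1-p2 over a circle
    of radius ``r`` centred at the origin.

    Returns ``(length, theta1, theta2, wrapped)``: the wrapped path length
    and the polar angles of the two tangent points, choosing the wrap side
    (arc direction) that minimizes total length.  If the straight segment
    clears the circle the straight length is returned with wrapped=False.
    """
    d1, d2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if d1 <= r or d2 <= r:
        raise GeometryError("muscle via point inside wrap obstacle")
    # distance from the origin to the segment
    seg = p2 - p1
    L = np.linalg.norm(seg)
    t = np.clip(-(p1 @ seg) / (L * L), 0.0, 1.0)
    closest = p1 + t * seg
    if np.linalg.norm(closest) >= r:
        return L, None, None, False
    t1 = np.sqrt(d1 * d1 - r * r)
    t2 = np.sqrt(d2 * d2 - r * r)
    phi1 = np.arctan2(p1[1], p1[0])
    phi2 = np.arctan2(p2[1], p2[0])
    beta1 = np.arccos(r / d1)  # angle between radius-to-p and radius-to-tangent-point
    beta2 = np.arccos(r / d2)
    best = None
    for side in (+1.0, -1.0):
        a1 = phi1 + side * beta1  # tangent point polar angle for this side
        a2 = phi2 - side * beta2
        arc = side * (a2 - a1)
        arc = np.mod(arc, 2 * np.pi)
        total = t1 + r * arc + t2
        if best is None or total < best[0]:
            best = (total, a1, a2)
    return best[0], best[1], best[2], True


def _wrap_sphere(p1: np.ndarray, p2: np.ndarray, obs_centre: np.ndarray, r: float):
    """Great-arc wrap over a sphere: the geodesic lies in the plane spanned
    by the two endpoints and the sphere centre, reducing to the planar
    circle construction."""
    a = p1 - obs_centre
    b = p2 - obs_centre
    normal = np.cross(a, b)
    nn = np.linalg.norm(normal)
    if nn < 1e-14:
        # endpoints collinear with the centre: the straight path pierces the
        # sphere through its middle; the wrap plane is degenerate
        raise GeometryError("sphere wrap degenerate: endpoints collinear with centre")
    e1 = a / np.linalg.norm(a)
    e3 = normal / nn
    e2 = np.cross(e3, e1)
    q1 = np.array([a @ e1, a @ e2])
    q2 = np.array([b @ e1, b @ e2])
    length, a1, a2, wrapped = _wrap_2d(q1, q2, r)
    pts = []
    if wrapped:
        for ang in np.linspace(a1, a2, 9):
            pts.append(obs_centre + r * (np.cos(ang) * e1 + np.sin(ang) * e2))
    return length, pts, wrapped


def _wrap_cylinder(p1: np.ndarray, p2: np.ndarray, obs_centre: np.ndarray, axis: np.ndarray, r: float):
    """Cylinder wrap: planar tangent geometry in the cross-section plane,
    with the axial coordinate distributed linearly along the unwrapped
    path (the geodesic on the developed cylinder surface)."""
    axis = axis / np.linalg.norm(axis)
    a = p1 - obs_centre
    b = p2 - obs_centre
    z1, z2 = a @ axis, b @ axis
    a_p = a - z1 * axis
    b_p = b - z2 * axis
    # in-plane basis
    if np.linalg.norm(a_p) < 1e-14 or np.linalg.norm(b_p) < 1e-14:
        raise GeometryError("cylinder wrap degenerate: point on the axis")
    e1 = a_p / np.linalg.norm(a_p)
    e2 = np.cross(axis, e1)
    q1 = np.array([a_p @ e1, a_p @ e2])
    q2 = np.array([b_p @ e1, b_p @ e2])
    plane_len, a1, a2, wrapped = _wrap_2d(q1, q2, r)
    if not wrapped:
        return np.linalg.norm(p2 - p1), [], False
    dz = z2 - z1
    length = np.sqrt(plane_len * plane_len + dz * dz)
    pts = []
    t1 = np.sqrt(q1 @ q1 - r * r)
    arc = plane_len - t1 - np.sqrt(q2 @ q2 - r * r)
    for k, ang in enumerate(np.linspace(a1, a2, 9)):
        s = (t1 + arc * k / 8.0) / plane_len  # fraction of in-plane path length
        z = z1 + s * dz
        pts.append(obs_centre + r * (np.cos(ang) * e1 + np.sin(ang) * e2) + z * axis)
    return length, pts, wrapped


@dataclass
class PathState:
    """Resolved muscle path at one pose."""

    length: float
    points: np.ndarray  # (k, 3) lab-frame polyline including wrap points
    wrapped: dict[str, bool]


def path_length(
    model: ModelConfig,
    muscle: Muscle | str,
    q: dict[str, np.ndarray] | None = None,
) -> PathState:
    """Musculotendon path length at pose ``q``, with wrap obstacles applied.

    Each straight segment that has a registered obstacle is tested for
    penetration; if it penetrates, the tangent–arc–tangent wrap replaces
    it.  The wrap side of a cylinder is the one minimizing path length.
    """
    if isinstance(muscle, str):
        muscle = model.muscle_by_name(muscle)
    fk = model.forward_kinematics(q)
    pts = []
    for seg, p_local in muscle.path.points:
        R, o = fk[seg]
        pts.append(o + R @ p_local)
    wraps_by_interval: dict[int, WrapObstacle] = {}
    for wname, idx in muscle.path.wraps:
        wraps_by_interval[idx] = model.wraps[wname]
    total = 0.0
    poly = [pts[0]]
    wrapped_flags: dict[str, bool] = {w: False for w, _ in muscle.path.wraps}
    for i in range(len(pts) - 1):
        p1, p2 = pts[i], pts[i + 1]
        obs = wraps_by_interval.get(i)
        if obs is None:
            total += np.linalg.norm(p2 - p1)
            poly.append(p2)
            continue
        Rw, ow = fk[obs.segment]
        centre = ow + Rw @ obs.centre
        if obs.kind == "sphere":
            length, mid_pts, wrapped = _wrap_sphere(p1, p2, centre, obs.radius)
        else:
            axis = Rw @ obs.axis
            length, mid_pts, wrapped = _wrap_cylinder(p1, p2, centre, axis, obs.radius)
        total += length
        poly.extend(mid_pts)
        poly.append(p2)
        wrapped_flags[obs.name] = wrapped_flags.get(obs.name, False) or wrapped
    if total <= 0:
        raise GeometryError(f"muscle {muscle.name}: non-positive path length")
    return PathState(length=float(total), points=np.array(poly), wrapped=wrapped_flags)


@dataclass
class MomentArmMatrix:
    """Moment arms r[i][j] (m): muscle i about generalized coordinate j."""

    r: np.ndarray  # (n_muscles, n_coords)
    muscles: list[str]
    coordinates: list[tuple[str, int]]

    def arm(self, muscle: str, joint: str, dof: int) -> float:
        return float(
            self.r[self.muscles.index(muscle), self.coordinates.index((joint, dof))]
        )


def moment_arms(
    model: ModelConfig,
    q: dict[str, np.ndarray] | None = None,
    h: float = 1e-6,
    muscles: list[Muscle] | None = None,
    coordinates: list[tuple[str, int]] | None = None,
    max_halvings: int = 5,
) -> MomentArmMatrix:
    """Tendon-excursion moment arms by central differences.

    ``r[i][j] = -dL_i/dq_j`` evaluated at step ``h``.  If a wrap
    engagement flips sign within ±h for some coordinate (detected as a
    wrapped-state mismatch between the two perturbed poses) the step is
    halved adaptively, warning after ``max_halvings`` halvings.
    """
    if h <= 0:
        raise ValueError("finite-difference step must be > 0")
    if muscles is None:
        muscles = model.muscles
    if coordinates is None:
        coordinates = model.coordinates()
    q = {k: np.asarray(v, dtype=float).copy() for k, v in (q or {}).items()}
    for jname, _ in coordinates:
        q.setdefault(jname, np.zeros(6))
    r = np.zeros((len(muscles), len(coordinates)))
    for jcol, (jname, dof) in enumerate(coordinates):
        for irow, mus in enumerate(muscles):
            if not _muscle_spans(model, mus, jname):
                continue
            step = h
            for attempt in range(max_halvings + 1):
                qp = {k: v.copy() for k, v in q.items()}
                qm = {k: v.copy() for k, v in q.items()}
                qp[jname][dof] += step
                qm[jname][dof] -= step
                sp = path_length(model, mus, qp)
                sm = path_length(model, mus, qm)
                if sp.wrapped == sm.wrapped or attempt == max_halvings:
                    if sp.wrapped != sm.wrapped:
                        warnings.warn(
                            f"moment arm of {mus.name} about {jname}[{dof}]: wrap state "
                            f"flips within ±{step}; result is one-sided in character"
                        )
                    r[irow, jcol] = -(sp.length - sm.length) / (2 * step)
                    break
                step *= 0.5
    return MomentArmMatrix(r=r, muscles=[m.name for m in muscles], coordinates=list(coordinates))


def _muscle_spans(model: ModelConfig, muscle: Muscle, joint_name: str) -> bool:
    """True if the joint lies on a chain between any two muscle attachments.

    Coordinates not spanned by a muscle get an exact zero moment arm
    without finite differencing.
    """
    j = model.joint_by_name(joint_name)
    # segments distal to the joint (subtree rooted at j.child)
    children = model.children()
    distal = set()
    stack = [j.child]
    while stack:
        s = stack.pop()
        distal.add(s)
        for cj in children.get(s, []):
            stack.append(cj.child)
    attach = {seg for seg, _ in muscle.path.points}
    wrap_segs = {model.wraps[w].segment for w, _ in muscle.path.wraps}
    touched = attach | wrap_segs
    return bool(touched & distal) and bool(touched - distal)


# ---------------------------------------------------------------------------
# Hill-type static force


def active_force_length(l_norm: np.ndarray | float) -> np.ndarray | float:
    """Active force-length curve: unimodal Gaussian, peak 1 at optimal length."""
    return np.exp(-(((np.asarray(l_norm) - 1.0) / FL_WIDTH) ** 2))


def passive_force_length(l_norm: np.ndarray | float) -> np.ndarray | float:
    """Passive elastic curve: zero at/below optimal length, exponential rise
    normalized to 1 at ``1 + PASSIVE_STRAIN``."""
    l = np.asarray(l_norm, dtype=float)
    scale = np.expm1(PASSIVE_SHAPE)
    out = np.where(l > 1.0, np.expm1(PASSIVE_SHAPE * (l - 1.0) / PASSIVE_STRAIN) / scale, 0.0)
    return out if out.ndim else float(out)


def fibre_state(l_mt: float, params: MuscleParams) -> tuple[float, float]:
    """Rigid-tendon fibre kinematics: (normalized fibre length, cos pennation).

    The tendon is inextensible at its slack length; the fibre spans the
    remainder with constant-thickness pennation
    (``w = fl * sin(alpha)`` held fixed).
    """
    slack = params.tendon_slack
    if slack is None:
        slack = params.tl if params.tl is not None else estimate_tendon_length(
            params.ml, params.fl, params.alpha
        )
    proj = l_mt - slack
    if proj <= 0:
        raise GeometryError("musculotendon length at or below tendon slack length")
    w = params.fl * np.sin(params.alpha)
    l_f = np.hypot(proj, w)
    cos_a = proj / l_f
    return l_f / params.fl, cos_a


def muscle_force(
    a: float,
    muscle: Muscle,
    l_mt: float | None = None,
    include_passive: bool = True,
) -> float:
    """Static Hill-type muscle force along the tendon (N).

    ``F = (a * f_L(l̃) + f_P(l̃)) * fmax * cos(alpha)`` with the rigid-tendon
    fibre length from the musculotendon path length; with ``l_mt=None`` the
    fibre is assumed at optimal length (isolated-muscle use).  Activation
    must lie in [0, 1]; force is linear and monotone non-decreasing in it.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    p = muscle.params
    if l_mt is None:
        l_norm, cos_a = 1.0, float(np.cos(p.alpha))
    else:
        l_norm, cos_a = fibre_state(l_mt, p)
    f = a * active_force_length(l_norm)
    if include_passive:
        f = f + passive_force_length(l_norm)
    return float(f * p.fmax * cos_a)
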