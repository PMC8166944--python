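"""Recursive Newton–Euler inverse dynamics for branched segment chains.

Given generalized coordinates, velocities, and accelerations for every
joint, plus measured external loads (ground reaction force at the centre of
pressure), the recursion runs an outward kinematic pass (orientations,
angular velocities/accelerations, linear accelerations) from the root and
an inward force/moment pass from the distal segments, yielding the net
intersegmental force and moment at every joint.  Gravity is included via
the standard trick of accelerating the root frame by ``-g``.  Double
precision is used throughout; the error accumulation inherent to the
recursion is cross-checked against an independent Lagrangian oracle in the
test suite.

Joint moments are reported about the child-frame origin.  ``newton_euler``
returns lab-frame components; :func:`express_in_joint_frames` rotates them
into the child segment's joint frame, where x is flexion/extension
(protraction/retraction), y abduction/adduction, and z axial rotation, and
:func:`apply_sign_convention` flips selected axes so that retractor,
adductor, and internal-rotation torques are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import PoseSeries, rot_x, rot_y, rot_z
from .model_core import ModelConfig, ReferenceError_

__all__ = [
    "ExternalLoadSeries",
    "TorqueSeries",
    "newton_euler",
    "express_in_joint_frames",
    "apply_sign_convention",
    "generalized_forces",
]

_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


@dataclass
class ExternalLoadSeries:
    """Measured external load (e.g. GRF) applied to one segment.

    ``force`` (N) and ``cop`` (m, lab frame) over time; ``free_moment``
    (Nm, lab frame) is optional and defaults to zero.  Force must be zero
    during swing samples; the centre of pressure must be finite whenever
    the force is non-zero.
    """

    applied_segment: str
    force: np.ndarray
    cop: np.ndarray
    free_moment: np.ndarray | None = None

    def __post_init__(self):
        self.force = np.atleast_2d(np.asarray(self.force, dtype=float))
        self.cop = np.atleast_2d(np.asarray(self.cop, dtype=float))
        if self.free_moment is None:
            self.free_moment = np.zeros_like(self.force)
        else:
            self.free_moment = np.atleast_2d(np.asarray(self.free_moment, dtype=float))
        loaded = np.linalg.norm(self.force, axis=1) > 0
        if not np.all(np.isfinite(self.cop[loaded])):
            raise ValueError("centre of pressure must be finite wherever force is non-zero")


@dataclass
class TorqueSeries:
    """Per-joint intersegmental moment (Nm) and force (N) over time.

    ``moment[joint]`` and ``force[joint]`` are ``(n, 3)`` arrays.  ``frame``
    records whether components are lab-frame or joint-local.
    """

    time: np.ndarray
    moment: dict[str, np.ndarray]
    force: dict[str, np.ndarray]
    frame: str = "lab"  # "lab" | "joint"
    sign_convention: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "TorqueSeries":
        return TorqueSeries(
            time=self.time.copy(),
            moment={k: v.copy() for k, v in self.moment.items()},
            force={k: v.copy() for k, v in self.force.items()},
            frame=self.frame,
            sign_convention={k: v.copy() for k, v in self.sign_convention.items()},
        )


def _joint_frame_kinematics(qj, qdj, qddj):
    """Relative rotation and body-frame angular velocity/acceleration.

    For the intrinsic XYZ sequence ``R = Rx(a) Ry(b) Rz(c)`` the relative
    angular velocity in the child body frame is
    ``w = a' Rz^T Ry^T ex + b' Rz^T ey + c' ez`` and its body-frame time
    derivative follows by differentiating the axis vectors.
    """
    a, b, c = qj[:3]
    ad, bd, cd = qdj[:3]
    add, bdd, cdd = qddj[:3]
    Rx, Ry, Rz = rot_x(a), rot_y(b), rot_z(c)
    R_rel = Rx @ Ry @ Rz
    u1 = Rz.T @ (Ry.T @ _EX)
    u2 = Rz.T @ _EY
    w_b = ad * u1 + bd * u2 + cd * _EZ
    u1dot = (-cd * _skew(_EZ) @ Rz.T @ Ry.T - bd * Rz.T @ _skew(_EY) @ Ry.T) @ _EX
    u2dot = -cd * _skew(_EZ) @ Rz.T @ _EY
    wdot_b = add * u1 + bdd * u2 + cdd * _EZ + ad * u1dot + bd * u2dot
    return R_rel, w_b, wdot_b


def newton_euler(
    model: ModelConfig,
    pose: PoseSeries,
    loads: list[ExternalLoadSeries] | ExternalLoadSeries | None = None,
) -> TorqueSeries:
    """Net intersegmental forces and moments by recursive Newton–Euler.

    Outward pass: lab-frame orientation, angular velocity/acceleration, and
    frame-origin acceleration of each segment, propagated root-to-leaves
    with the full transport, centripetal, and Coriolis terms for
    translational DOFs.  Inward pass (depth-first post-order): segment
    inertial wrenches, external loads, and child joint wrenches are summed
    from the leaves toward the root.  The residual wrench at joints rooted
    on ground is reported, not zeroed — it plays the role of the global
    reserve actuators.

    Moments are about each joint's (translated) child-frame origin, in the
    lab frame.
    """
    if loads is None:
        loads = []
    if isinstance(loads, ExternalLoadSeries):
        loads = [loads]
    for ld in loads:
        if ld.applied_segment not in model.segments:
            raise ReferenceError_(f"load applied to unknown segment {ld.applied_segment!r}")
    order = model.joint_order()
    for j in order:
        if j.n_dofs and j.name not in pose.q:
            raise ValueError(f"pose is missing coordinates for joint {j.name!r}")
        if j.name in pose.q and j.name not in pose.qd:
            raise ValueError(
                f"pose is missing velocity/acceleration data for joint {j.name!r}; "
                "call PoseSeries.fill_derivatives() or supply them"
            )
    n = pose.n_samples
    g = model.gravity
    loads_by_seg: dict[str, list[ExternalLoadSeries]] = {}
    for ld in loads:
        loads_by_seg.setdefault(ld.applied_segment, []).append(ld)

    moment = {j.name: np.zeros((n, 3)) for j in order}
    force = {j.name: np.zeros((n, 3)) for j in order}

    children = model.children()
    for i in range(n):
        q, qd, qdd = pose.frame(i)
        # outward kinematic pass
        state = {
            model.ground: dict(
                R=np.eye(3), o=np.zeros(3), w=np.zeros(3), al=np.zeros(3),
                a_o=-g,  # root acceleration -g folds gravity into the wrenches
            )
        }
        for j in order:
            par = state[j.parent]
            qj = q.get(j.name, np.zeros(6))
            qdj = qd.get(j.name, np.zeros(6))
            qddj = qdd.get(j.name, np.zeros(6))
            R_rel, w_b, wdot_b = _joint_frame_kinematics(qj, qdj, qddj)
            R_pf = par["R"] @ j.frame_rotation
            R_c = R_pf @ R_rel
            r_p = j.frame_translation + j.frame_rotation @ qj[3:6]  # in parent frame
            d = par["R"] @ r_p
            v_rel = R_pf @ qdj[3:6]
            a_rel = R_pf @ qddj[3:6]
            w_rel = R_c @ w_b
            w_c = par["w"] + w_rel
            al_c = par["al"] + np.cross(par["w"], w_rel) + R_c @ wdot_b
            a_o = (
                par["a_o"]
                + np.cross(par["al"], d)
                + np.cross(par["w"], np.cross(par["w"], d))
                + 2.0 * np.cross(par["w"], v_rel)
                + a_rel
            )
            state[j.child] = dict(R=R_c, o=par["o"] + d, w=w_c, al=al_c, a_o=a_o)

        # inward force/moment pass, leaves to root
        for j in reversed(order):
            st = state[j.child]
            seg = model.segments[j.child]
            R, o, w, al, a_o = st["R"], st["o"], st["w"], st["al"], st["a_o"]
            c_lab = R @ seg.com
            a_com = a_o + np.cross(al, c_lab) + np.cross(w, np.cross(w, c_lab))
            I_lab = R @ seg.inertia @ R.T
            F_net = seg.mass * a_com
            N_net = I_lab @ al + np.cross(w, I_lab @ w)
            f = F_net.copy()
            nmom = N_net + np.cross(c_lab, F_net)
            for ld in loads_by_seg.get(j.child, []):
                fe = ld.force[i]
                f -= fe
                if np.linalg.norm(fe) > 0:
                    nmom -= np.cross(ld.cop[i] - o, fe)
                nmom -= ld.free_moment[i]
            for cj in children.get(j.child, []):
                f += force[cj.name][i]
                nmom += moment[cj.name][i] + np.cross(
                    state[cj.child]["o"] - o, force[cj.name][i]
                )
            force[j.name][i] = f
            moment[j.name][i] = nmom
    return TorqueSeries(time=pose.time.copy(), moment=moment, force=force, frame="lab")


def express_in_joint_frames(torques: TorqueSeries, model: ModelConfig, pose: PoseSeries) -> TorqueSeries:
    """Rotate lab-frame joint wrenches into each child segment's frame.

    After this, component x is flexion/extension (protraction/retraction),
    y abduction/adduction, z axial rotation, matching the local axis
    convention of the model.
    """
    if torques.frame != "lab":
        raise ValueError("input torques must be lab-frame")
    out = torques.copy()
    order = model.joint_order()
    for i in range(pose.n_samples):
        q, _, _ = pose.frame(i)
        fk = model.forward_kinematics(q)
        for j in order:
            R = fk[j.child][0]
            out.moment[j.name][i] = R.T @ torques.moment[j.name][i]
            out.force[j.name][i] = R.T @ torques.force[j.name][i]
    out.frame = "joint"
    return out


#: Default per-axis sign maps making retractor (x), adductor (y), and
#: internal-rotation (z) torques positive.  A retractor torque flexes the
#: shoulder, extends the elbow, and flexes the carpal joint, so the
#: flexion/extension axis flips at alternating forelimb joints.
DEFAULT_SIGN_CONVENTION = {
    "scapula": np.array([1.0, 1.0, 1.0]),
    "shoulder": np.array([1.0, 1.0, 1.0]),
    "elbow": np.array([-1.0, 1.0, 1.0]),
    "carpal": np.array([1.0, 1.0, 1.0]),
    "forepaw": np.array([-1.0, 1.0, 1.0]),
}


def apply_sign_convention(
    torques: TorqueSeries,
    convention: dict[str, np.ndarray] | None = None,
) -> TorqueSeries:
    """Apply per-joint axis sign flips to joint-frame torques.

    ``convention`` maps joint name (or its suffix-stripped stem) to a
     3-vector of ±1.  Joints without a registered convention keep raw signs
    and are collected in the returned series' ``sign_convention`` with a
    unit map (a warning case, not an error).  The map is its own inverse:
    applying it twice restores the input.
    """
    conv = DEFAULT_SIGN_CONVENTION if convention is None else convention
    out = torques.copy()
    for name in out.moment:
        stem = name
        for suffix in ("_l", "_r"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        s = conv.get(name, conv.get(stem))
        if s is None:
            s = np.ones(3)
        s = np.asarray(s, dtype=float)
        out.moment[name] = out.moment[name] * s
        out.sign_convention[name] = s
    return out


def generalized_forces(
    torques: TorqueSeries,
    model: ModelConfig,
    pose: PoseSeries,
    coordinates: list[tuple[str, int]] | None = None,
) -> dict[tuple[str, int], np.ndarray]:
    """Project joint wrenches onto each enabled DOF axis.

    For the intrinsic XYZ sequence the instantaneous rotation axes are
    ``R_pf ex``, ``R_pf Rx ey``, ``R_pf Rx Ry ez`` (lab frame) and the
    translation axes are the joint-frame basis vectors; the projection of
    the intersegmental moment (about the joint origin) or force on these
    axes gives the generalized force conjugate to each coordinate —
    directly comparable with a Lagrangian formulation.
    """
    if torques.frame != "lab":
        raise ValueError("generalized_forces expects lab-frame torques")
    order = model.joint_order()
    wanted: dict[str, list[int]] = {}
    if coordinates is None:
        for j in order:
            wanted[j.name] = j.enabled()
    else:
        for jname, k in coordinates:
            wanted.setdefault(jname, []).append(k)
    out = {
        (jname, k): np.zeros(pose.n_samples)
        for jname, ks in wanted.items()
        for k in ks
    }
    for i in range(pose.n_samples):
        q, _, _ = pose.frame(i)
        fk = model.forward_kinematics(q)
        for j in order:
            if j.name not in wanted:
                continue
            Rp = fk[j.parent][0]
            R_pf = Rp @ j.frame_rotation
            qj = np.asarray(q.get(j.name, np.zeros(6)))
            Rx, Ry = rot_x(qj[0]), rot_y(qj[1])
            axes = {
                0: R_pf @ _EX,
                1: R_pf @ (Rx @ _EY),
                2: R_pf @ (Rx @ (Ry @ _EZ)),
            }
            for k in wanted[j.name]:
                if k < 3:
                    out[(j.name, k)][i] = axes[k] @ torques.moment[j.name][i]
                else:
                    out[(j.name, k)][i] = (R_pf @ np.eye(3)[:, k - 3]) @ torques.force[
                        j.name
                    ][i]
    return out
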