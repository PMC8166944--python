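"""Domain types for the articulated musculoskeletal model.

A model is a rooted tree of rigid segments connected by joints.  Each joint
carries six per-axis DOF switches — three rotations (intrinsic XYZ Cardan)
and three translations — plus per-DOF reserve-actuator bounds.  Muscles are
polylines of attachment points on segments, optionally wrapped over sphere
or cylinder obstacles; spheres constrain ball-and-socket joints, cylinders
constrain hinge joints.

Frame conventions: a joint places the child frame at
``o_child = o_parent + R_parent @ (t_frame + R_frame @ t_q)`` and
``R_child = R_parent @ R_frame @ Rx(rx) @ Ry(ry) @ Rz(rz)``, where
``(rx, ry, rz, tx, ty, tz)`` are the joint's generalized coordinates
(disabled DOFs pinned at zero).  Local x is protraction/retraction
(flexion/extension), y abduction/adduction, z axial rotation / mediolateral.
Gravity defaults to (0, -9.81, 0) m/s²; units are SI throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import cardan_matrix

__all__ = [
    "DOF_NAMES",
    "Segment",
    "Joint",
    "WrapObstacle",
    "MusclePath",
    "MuscleParams",
    "Muscle",
    "ModelConfig",
    "TopologyError",
    "ReferenceError_",
    "assemble_model",
    "mirror_limb",
    "count_dofs",
]

DOF_NAMES = ("rx", "ry", "rz", "tx", "ty", "tz")
GROUND = "ground"

_MIRROR = np.diag([1.0, 1.0, -1.0])  # sagittal reflection, mediolateral = z


class TopologyError(ValueError):
    """Joint graph is not a rooted tree."""


class ReferenceError_(KeyError):
    """A muscle point, wrap, or joint references an unknown element."""


def _vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


@dataclass(frozen=True)
class Segment:
    """Rigid body: mass, centre of mass, and inertia in the segment frame."""

    name: str
    mass: float = 0.0
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    inertia: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    length_scale: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "com", _vec3(self.com))
        I = np.asarray(self.inertia, dtype=float)
        if I.shape == (3,):
            I = np.diag(I)
        if I.shape != (3, 3):
            raise ValueError(f"segment {self.name}: inertia must be 3x3 or diagonal 3")
        object.__setattr__(self, "inertia", I)
        if self.mass < 0:
            raise ValueError(f"segment {self.name}: mass must be >= 0")
        if not np.allclose(I, I.T, atol=1e-12):
            raise ValueError(f"segment {self.name}: inertia must be symmetric")
        w = np.linalg.eigvalsh(I)
        if w[0] < -1e-12:
            raise ValueError(f"segment {self.name}: inertia must be positive semidefinite")
        # principal moments of a physical rigid body satisfy triangle inequalities
        a, b, c = np.maximum(w, 0.0)
        if a + b < c - 1e-9 * max(c, 1.0):
            raise ValueError(
                f"segment {self.name}: principal moments violate the triangle inequality"
            )


@dataclass(frozen=True)
class Joint:
    """Connection parent -> child with per-axis DOF switches.

    ``dof_flags`` and ``actuator_bounds`` follow the order
    ``(rx, ry, rz, tx, ty, tz)``.  Bounds are the maximum reserve torque
    (Nm, rotations) or force (N, translations) of the joint's non-biological
    actuator; ``bounds_verified=False`` marks values carried over from
    sources with ambiguous typography.
    """

    name: str
    parent: str
    child: str
    frame_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    dof_flags: tuple[bool, ...] = (False,) * 6
    actuator_bounds: np.ndarray = field(default_factory=lambda: np.zeros(6))
    bounds_verified: bool = True

    def __post_init__(self):
        object.__setattr__(self, "frame_translation", _vec3(self.frame_translation))
        R = np.asarray(self.frame_rotation, dtype=float).reshape(3, 3)
        object.__setattr__(self, "frame_rotation", R)
        flags = tuple(bool(f) for f in self.dof_flags)
        if len(flags) != 6:
            raise ValueError(f"joint {self.name}: dof_flags must have 6 entries")
        object.__setattr__(self, "dof_flags", flags)
        b = np.asarray(self.actuator_bounds, dtype=float).reshape(6)
        if np.any(b < 0):
            raise ValueError(f"joint {self.name}: actuator bounds must be >= 0")
        object.__setattr__(self, "actuator_bounds", b)

    @property
    def n_dofs(self) -> int:
        return sum(self.dof_flags)

    def enabled(self) -> list[int]:
        return [i for i, f in enumerate(self.dof_flags) if f]


@dataclass(frozen=True)
class WrapObstacle:
    """Sphere or cylinder a muscle path may not penetrate."""

    name: str
    kind: str  # "sphere" | "cylinder"
    segment: str
    centre: np.ndarray
    radius: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        if self.kind not in ("sphere", "cylinder"):
            raise ValueError(f"wrap {self.name}: kind must be sphere or cylinder")
        if not self.radius > 0:
            raise ValueError(f"wrap {self.name}: radius must be > 0")
        object.__setattr__(self, "centre", _vec3(self.centre))
        a = _vec3(self.axis)
        n = np.linalg.norm(a)
        if self.kind == "cylinder" and abs(n - 1.0) > 1e-9:
            a = a / n
        object.__setattr__(self, "axis", a)


@dataclass(frozen=True)
class MusclePath:
    """Ordered attachment points (origin to insertion) with optional wraps.

    ``wraps`` lists ``(obstacle_name, insert_after)`` pairs: the obstacle is
    considered for the straight segment between path points ``insert_after``
    and ``insert_after + 1``.
    """

    name: str
    points: tuple[tuple[str, np.ndarray], ...]
    wraps: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError(f"muscle {self.name}: needs at least 2 path points")
        pts = tuple((seg, _vec3(p)) for seg, p in self.points)
        object.__setattr__(self, "points", pts)
        for _, idx in self.wraps:
            if not 0 <= idx < len(pts) - 1:
                raise ValueError(f"muscle {self.name}: wrap interval out of range")


@dataclass(frozen=True)
class MuscleParams:
    """Morphometric and Hill-model parameters of one muscle.

    m muscle mass (kg), ml muscle-tendon length (m), fl fibre/fascicle
    length (m), alpha pennation angle (rad), pcsa (m²), fmax maximum
    isometric force (N), tl tendon length (m), tendon_slack slack length
    used by the rigid-tendon model (m, defaults to tl).
    """

    m: float = 0.0
    ml: float = 0.1
    fl: float = 0.1
    alpha: float = 0.0
    pcsa: float = 1e-4
    fmax: float = 100.0
    tl: float | None = None
    tendon_slack: float | None = None

    def __post_init__(self):
        if not (0 <= self.alpha < np.pi / 2):
            raise ValueError("pennation angle must lie in [0, pi/2)")
        if not (0 < self.fl <= self.ml):
            raise ValueError("fibre length must satisfy 0 < fl <= ml")
        if self.fmax <= 0 or self.pcsa <= 0:
            raise ValueError("fmax and pcsa must be > 0")
        if self.tl is not None and self.tl < 0:
            raise ValueError("tendon length must be >= 0")


@dataclass(frozen=True)
class Muscle:
    path: MusclePath
    params: MuscleParams

    @property
    def name(self) -> str:
        return self.path.name


@dataclass
class ModelConfig:
    """Validated mechanical description: segments, joints, muscles, wraps."""

    segments: dict[str, Segment]
    joints: list[Joint]
    muscles: list[Muscle] = field(default_factory=list)
    wraps: dict[str, WrapObstacle] = field(default_factory=dict)
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, -9.81, 0.0]))
    ground: str = GROUND

    def __post_init__(self):
        self.gravity = _vec3(self.gravity)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.ground not in self.segments:
            self.segments[self.ground] = Segment(self.ground)
        child_of: dict[str, str] = {}
        for j in self.joints:
            for end in (j.parent, j.child):
                if end not in self.segments:
                    raise ReferenceError_(f"joint {j.name}: unknown segment {end!r}")
            if j.child in child_of:
                raise TopologyError(f"segment {j.child} has two parent joints")
            child_of[j.child] = j.parent
        # every non-ground segment with a joint chain must reach ground without cycles
        for seg in self.segments:
            seen = set()
            cur = seg
            while cur != self.ground and cur in child_of:
                if cur in seen:
                    raise TopologyError(f"cycle in joint graph at segment {cur}")
                seen.add(cur)
                cur = child_of[cur]
            if cur != self.ground and cur in seen:
                raise TopologyError(f"cycle in joint graph at segment {cur}")
        roots = {
            s
            for s in self.segments
            if s != self.ground and s not in child_of
        }
        if roots and any(j.parent in roots for j in self.joints):
            # a segment that parents joints but hangs from nothing is a second root
            bad = sorted(r for r in roots if any(j.parent == r for j in self.joints))
            if bad:
                raise TopologyError(f"second root segment(s): {bad}")
        for w in self.wraps.values():
            if w.segment not in self.segments:
                raise ReferenceError_(f"wrap {w.name}: unknown segment {w.segment!r}")
        for mus in self.muscles:
            for seg, _ in mus.path.points:
                if seg not in self.segments:
                    raise ReferenceError_(
                        f"muscle {mus.name}: path point on unknown segment {seg!r}"
                    )
            for wname, _ in mus.path.wraps:
                if wname not in self.wraps:
                    raise ReferenceError_(
                        f"muscle {mus.name}: unknown wrap obstacle {wname!r}"
                    )

    # -- structure queries --------------------------------------------------

    def joint_by_name(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise ReferenceError_(f"no joint named {name!r}")

    def joint_order(self) -> list[Joint]:
        """Joints in topological (root-outward) order."""
        placed = {self.ground}
        remaining = list(self.joints)
        ordered: list[Joint] = []
        while remaining:
            progressed = False
            for j in list(remaining):
                if j.parent in placed:
                    ordered.append(j)
                    placed.add(j.child)
                    remaining.remove(j)
                    progressed = True
            if not progressed:
                raise TopologyError("joint graph is not rooted at ground")
            # deterministic order independent of input ordering is not required;
            # DOF count is order-invariant regardless
        return ordered

    def children(self) -> dict[str, list[Joint]]:
        out: dict[str, list[Joint]] = {}
        for j in self.joints:
            out.setdefault(j.parent, []).append(j)
        return out

    def ground_joints(self) -> list[Joint]:
        return [j for j in self.joints if j.parent == self.ground]

    def coordinates(self, include_ground: bool = True) -> list[tuple[str, int]]:
        """Flat list of enabled (joint name, dof index) pairs."""
        coords = []
        for j in self.joint_order():
            if not include_ground and j.parent == self.ground:
                continue
            coords.extend((j.name, i) for i in j.enabled())
        return coords

    def muscle_by_name(self, name: str) -> Muscle:
        for m in self.muscles:
            if m.name == name:
                return m
        raise ReferenceError_(f"no muscle named {name!r}")

    # -- kinematics ---------------------------------------------------------

    def forward_kinematics(
        self, q: dict[str, np.ndarray] | None = None
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Lab-frame pose of every segment: name -> (R, origin).

        ``q`` maps joint name to its 6-vector of generalized coordinates
        (missing joints held at zero).
        """
        q = q or {}
        pose = {self.ground: (np.eye(3), np.zeros(3))}
        for j in self.joint_order():
            Rp, op = pose[j.parent]
            qj = np.asarray(q.get(j.name, np.zeros(6)), dtype=float)
            t_q = qj[3:6]
            o = op + Rp @ (j.frame_translation + j.frame_rotation @ t_q)
            R = Rp @ j.frame_rotation @ cardan_matrix(*qj[:3])
            pose[j.child] = (R, o)
        return pose

    def restrict_muscles_to(self, segment_names: set[str]) -> "ModelConfig":
        """Sub-model: all segments and masses kept, muscles restricted.

        A muscle belongs to the sub-model when any of its attachment points
        lies on one of ``segment_names`` — extrinsic muscles originating on
        the trunk are kept with the limb they insert on.
        """
        muscles = [
            m
            for m in self.muscles
            if any(seg in segment_names for seg, _ in m.path.points)
        ]
        return ModelConfig(
            segments=dict(self.segments),
            joints=list(self.joints),
            muscles=muscles,
            wraps=dict(self.wraps),
            gravity=self.gravity.copy(),
            ground=self.ground,
        )


# ---------------------------------------------------------------------------
# assembly from structured config

_SEGMENT_KEYS = {"name", "mass", "com", "inertia", "length_scale"}
_JOINT_KEYS = {"name", "parent", "child", "translation", "rotation", "dofs", "bounds"}
_WRAP_KEYS = {"name", "kind", "segment", "centre", "axis", "radius"}
_MUSCLE_KEYS = {"name", "points", "wraps", "params"}
_PARAM_KEYS = {"m", "ml", "fl", "alpha", "pcsa", "fmax", "tl", "tendon_slack"}
SCHEMA_VERSION = 1


def _check_keys(d: dict, allowed: set, what: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"{what}: unknown keys {sorted(unknown)}")


def assemble_model(spec: dict) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a structured config.

    The config is a mapping with a ``schema_version`` header key and
    ``segments`` / ``joints`` / ``wraps`` / ``muscles`` sections (see the
    packaged examples).  Unknown keys are errors, not warnings.
    """
    _check_keys(
        spec,
        {"schema_version", "gravity", "segments", "joints", "wraps", "muscles"},
        "model config",
    )
    if spec.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"model config must declare schema_version: {SCHEMA_VERSION}"
        )
    segments: dict[str, Segment] = {}
    for s in spec.get("segments", []):
        _check_keys(s, _SEGMENT_KEYS, f"segment {s.get('name')}")
        seg = Segment(
            name=s["name"],
            mass=float(s.get("mass", 0.0)),
            com=s.get("com", (0, 0, 0)),
            inertia=s.get("inertia", np.zeros((3, 3))),
            length_scale=float(s.get("length_scale", 1.0)),
        )
        segments[seg.name] = seg
    joints: list[Joint] = []
    for jd in spec.get("joints", []):
        _check_keys(jd, _JOINT_KEYS, f"joint {jd.get('name')}")
        dofs = jd.get("dofs", [])
        for d in dofs:
            if d not in DOF_NAMES:
                raise ValueError(f"joint {jd.get('name')}: unknown DOF {d!r}")
        flags = tuple(d in dofs for d in DOF_NAMES)
        bounds = np.zeros(6)
        for d, v in (jd.get("bounds") or {}).items():
            if d not in DOF_NAMES:
                raise ValueError(f"joint {jd.get('name')}: unknown bound DOF {d!r}")
            bounds[DOF_NAMES.index(d)] = float(v)
        rot = jd.get("rotation")
        R = cardan_matrix(*rot) if rot is not None else np.eye(3)
        joints.append(
            Joint(
                name=jd["name"],
                parent=jd["parent"],
                child=jd["child"],
                frame_translation=jd.get("translation", (0, 0, 0)),
                frame_rotation=R,
                dof_flags=flags,
                actuator_bounds=bounds,
            )
        )
    wraps: dict[str, WrapObstacle] = {}
    for wd in spec.get("wraps", []):
        _check_keys(wd, _WRAP_KEYS, f"wrap {wd.get('name')}")
        w = WrapObstacle(
            name=wd["name"],
            kind=wd["kind"],
            segment=wd["segment"],
            centre=wd["centre"],
            radius=float(wd["radius"]),
            axis=wd.get("axis", (0, 0, 1)),
        )
        wraps[w.name] = w
    muscles: list[Muscle] = []
    for md in spec.get("muscles", []):
        _check_keys(md, _MUSCLE_KEYS, f"muscle {md.get('name')}")
        pd = md.get("params", {})
        _check_keys(pd, _PARAM_KEYS, f"muscle {md.get('name')} params")
        path = MusclePath(
            name=md["name"],
            points=tuple((p[0], p[1]) for p in md["points"]),
            wraps=tuple((w["obstacle"], int(w["after"])) for w in md.get("wraps", [])),
        )
        muscles.append(Muscle(path=path, params=MuscleParams(**pd)))
    return ModelConfig(
        segments=segments,
        joints=joints,
        muscles=muscles,
        wraps=wraps,
        gravity=spec.get("gravity", (0.0, -9.81, 0.0)),
    )


# ---------------------------------------------------------------------------
# mirroring and DOF counting


def _mirror_name(name: str, left: str, right: str) -> str:
    if name.endswith(left):
        return name[: -len(left)] + right
    return name


def mirror_limb(
    model: ModelConfig,
    plane: str = "sagittal",
    left_suffix: str = "_l",
    right_suffix: str = "_r",
) -> ModelConfig:
    """Add a mirrored right side for every left-suffixed element.

    Geometry is reflected through the sagittal plane (mediolateral z axis
    negated); muscle parameters are copied unchanged, so the right limb is
    an exact mirrored copy of the left.  Rotation frames transform as
    ``S R S`` with ``S = diag(1, 1, -1)`` (a proper rotation again).
    """
    if plane != "sagittal":
        raise ValueError("only sagittal mirroring is supported")
    S = _MIRROR

    def mirror_R(R: np.ndarray) -> np.ndarray:
        return S @ R @ S

    segs = dict(model.segments)
    for s in model.segments.values():
        if s.name.endswith(left_suffix):
            segs[_mirror_name(s.name, left_suffix, right_suffix)] = replace(
                s,
                name=_mirror_name(s.name, left_suffix, right_suffix),
                com=S @ s.com,
                inertia=S @ s.inertia @ S,
            )
    joints = list(model.joints)
    for j in model.joints:
        if j.child.endswith(left_suffix):
            joints.append(
                replace(
                    j,
                    name=_mirror_name(j.name, left_suffix, right_suffix),
                    parent=_mirror_name(j.parent, left_suffix, right_suffix),
                    child=_mirror_name(j.child, left_suffix, right_suffix),
                    frame_translation=S @ j.frame_translation,
                    frame_rotation=mirror_R(j.frame_rotation),
                )
            )
    wraps = dict(model.wraps)
    for w in model.wraps.values():
        if w.name.endswith(left_suffix):
            wraps[_mirror_name(w.name, left_suffix, right_suffix)] = replace(
                w,
                name=_mirror_name(w.name, left_suffix, right_suffix),
                segment=_mirror_name(w.segment, left_suffix, right_suffix),
                centre=S @ w.centre,
                axis=S @ w.axis,
            )
    muscles = list(model.muscles)
    for m in model.muscles:
        if m.name.endswith(left_suffix):
            path = MusclePath(
                name=_mirror_name(m.name, left_suffix, right_suffix),
                points=tuple(
                    (_mirror_name(seg, left_suffix, right_suffix), S @ p)
                    for seg, p in m.path.points
                ),
                wraps=tuple(
                    (_mirror_name(w, left_suffix, right_suffix), i)
                    for w, i in m.path.wraps
                ),
            )
            muscles.append(Muscle(path=path, params=m.params))
    return ModelConfig(
        segments=segs,
        joints=joints,
        muscles=muscles,
        wraps=wraps,
        gravity=model.gravity.copy(),
        ground=model.ground,
    )


def count_dofs(model: ModelConfig, include_ground: bool = False) -> int:
    """Total enabled DOFs, optionally including the ground joint(s)."""
    total = 0
    for j in model.joints:
        if not include_ground and j.parent == model.ground:
            continue
        total += j.n_dofs
    return total
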