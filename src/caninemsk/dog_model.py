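"""Packaged whole-dog model configuration.

Topology of a walking-dog musculoskeletal model at maximum mobility:

* ground -> carrier: free-floating base, 3 translational DOFs (the
  "global" joint with its 0.5 N force actuators); excluded from the
  model's DOF count.
* axial skeleton: thorax, head, abdomen, tail with 3 rotational DOFs each
  (12 axial DOFs; vertebral motion is not modelled).
* each forelimb: scapula 5 (3 rotations + anterior-posterior and vertical
  translation — the scapula rides on a muscle sling, not a bony joint),
  shoulder 3, elbow 2, carpal 2, forepaw 3 = 15 DOFs.
* each hindlimb: pelvis 5, hip 3, stifle 2, tarsal 2, hindpaw 3, toes 6
  (lumped) = 21 DOFs.  The per-joint hindlimb split is a configuration
  choice constrained by the whole-model total, not reported anatomy.

Total: 12 + 2x15 + 2x21 = 84 DOFs at maximum mobility.

The muscle registry holds 67 muscles per side (134 bilaterally): the major
fore- and hindlimb muscles plus the locomotion-relevant epaxial muscles;
head, belly, and toe muscles are omitted.  Attachment coordinates and
inertial values are synthetic placeholders on the real topology — counts,
tree structure, DOF allocation, and actuator-bound placement are the
modelled content here, not individual-specific geometry.

Forelimb reserve-actuator bounds follow the published parameter map; the
per-axis cell values are typographically ambiguous in the source and are
therefore marked unverified on the joints carrying them.
"""

from __future__ import annotations

import numpy as np

from .model_core import (
    Joint,
    ModelConfig,
    Muscle,
    MuscleParams,
    MusclePath,
    Segment,
    WrapObstacle,
    count_dofs,
    mirror_limb,
)

__all__ = [
    "build_dog_model",
    "build_forelimb_model",
    "FORELIMB_DOF_BREAKDOWN",
    "FORELIMB_ACTUATOR_BOUNDS",
    "MUSCLES_PER_SIDE",
]

#: Printed per-joint DOF allocation of the left forelimb.
FORELIMB_DOF_BREAKDOWN = {
    "scapula": 5,
    "shoulder": 3,
    "elbow": 2,
    "carpal": 2,
    "forepaw": 3,
}

#: Reserve-actuator bounds (Nm for rotations, N for translations) of the
#: forelimb parameter map.  DOF order (rx, ry, rz, tx, ty, tz); zeros mark
#: disabled DOFs.  Values are carried as read from an ambiguous table and
#: flagged unverified on the joints.
FORELIMB_ACTUATOR_BOUNDS = {
    "global": {"tx": 0.5, "ty": 0.5, "tz": 0.5},
    "scapula": {"rx": 5.0, "ry": 5.0, "rz": 5.0, "tx": 0.00005, "ty": 0.5},
    "shoulder": {"rx": 0.0005, "ry": 5.0, "rz": 5.0},
    "elbow": {"rx": 1.0, "ry": 5.0},
    "carpal": {"rx": 5.0, "rz": 1.0},
    "forepaw": {"rx": 0.005, "ry": 0.005, "rz": 0.0005},
}

MUSCLES_PER_SIDE = 67

_DOF = {"rx": 0, "ry": 1, "rz": 2, "tx": 3, "ty": 4, "tz": 5}


def _flags(dofs: list[str]) -> tuple[bool, ...]:
    f = [False] * 6
    for d in dofs:
        f[_DOF[d]] = True
    return tuple(f)


def _bounds(d: dict[str, float]) -> np.ndarray:
    b = np.zeros(6)
    for k, v in d.items():
        b[_DOF[k]] = v
    return b


def _seg(name, mass, length, half_width=0.02):
    # generic box-ish inertia about the COM; placeholder magnitudes
    a = mass * (length**2 + half_width**2) / 12
    b = mass * (2 * half_width**2) / 12
    return Segment(name, mass=mass, com=(0.0, -length / 2, 0.0), inertia=np.diag([a, b, a]))


# (name, origin segment, insertion segment, optional wrap)  — left side.
# Latin names with underscores; synthetic attachment coordinates are
# assigned formulaically below.
_FORELIMB_MUSCLES = [
    ("m_trapezius_pars_cervicalis", "thorax", "scapula_l", None),
    ("m_trapezius_pars_thoracica", "thorax", "scapula_l", None),
    ("m_rhomboideus_pars_cervicalis", "thorax", "scapula_l", None),
    ("m_rhomboideus_pars_thoracica", "thorax", "scapula_l", None),
    ("m_omotransversarius", "thorax", "scapula_l", None),
    ("m_serratus_ventralis_cervicis_1", "thorax", "scapula_l", None),
    ("m_serratus_ventralis_cervicis_2", "thorax", "scapula_l", None),
    ("m_serratus_ventralis_thoracis_1", "thorax", "scapula_l", None),
    ("m_serratus_ventralis_thoracis_2", "thorax", "scapula_l", None),
    ("m_latissimus_dorsi", "thorax", "humerus_l", None),
    ("m_pectoralis_superficialis", "thorax", "humerus_l", None),
    ("m_pectoralis_profundus", "thorax", "humerus_l", None),
    ("m_deltoideus_pars_scapularis", "scapula_l", "humerus_l", None),
    ("m_deltoideus_pars_acromialis", "scapula_l", "humerus_l", None),
    ("m_supraspinatus", "scapula_l", "humerus_l", None),
    ("m_infraspinatus", "scapula_l", "humerus_l", None),
    ("m_teres_major", "scapula_l", "humerus_l", None),
    ("m_subscapularis", "scapula_l", "humerus_l", "shoulder_sphere_l"),
    ("m_biceps_brachii", "scapula_l", "antebrachium_l", "shoulder_sphere_l"),
    ("m_brachialis", "humerus_l", "antebrachium_l", None),
    ("m_triceps_brachii_caput_longum", "scapula_l", "antebrachium_l", "elbow_cyl_l"),
    ("m_triceps_brachii_caput_laterale", "humerus_l", "antebrachium_l", "elbow_cyl_l"),
    ("m_triceps_brachii_caput_mediale", "humerus_l", "antebrachium_l", None),
    ("m_triceps_brachii_caput_accessorium", "humerus_l", "antebrachium_l", None),
    ("m_anconeus", "humerus_l", "antebrachium_l", None),
    ("m_pronator_teres", "humerus_l", "antebrachium_l", None),
    ("m_extensor_carpi_radialis", "humerus_l", "forepaw_l", None),
    ("m_flexor_carpi_radialis", "humerus_l", "forepaw_l", None),
    ("m_flexor_carpi_ulnaris", "humerus_l", "forepaw_l", None),
    ("m_extensor_carpi_ulnaris", "humerus_l", "forepaw_l", None),
    ("m_extensor_digitorum_communis", "humerus_l", "digits_l", None),
    ("m_flexor_digitorum_superficialis", "humerus_l", "digits_l", None),
    ("m_flexor_digitorum_profundus", "antebrachium_l", "digits_l", None),
]

_HINDLIMB_MUSCLES = [
    ("m_gluteus_superficialis", "pelvis_l", "femur_l", None),
    ("m_gluteus_medius", "pelvis_l", "femur_l", None),
    ("m_gluteus_profundus", "pelvis_l", "femur_l", None),
    ("m_tensor_fasciae_latae", "pelvis_l", "femur_l", None),
    ("m_iliopsoas", "abdomen", "femur_l", None),
    ("m_sartorius_pars_cranialis", "pelvis_l", "tibia_l", None),
    ("m_sartorius_pars_caudalis", "pelvis_l", "tibia_l", None),
    ("m_pectineus", "pelvis_l", "femur_l", None),
    ("m_adductor_magnus", "pelvis_l", "femur_l", None),
    ("m_gracilis", "pelvis_l", "tibia_l", None),
    ("m_semimembranosus", "pelvis_l", "tibia_l", None),
    ("m_semitendinosus", "pelvis_l", "tibia_l", None),
    ("m_biceps_femoris", "pelvis_l", "tibia_l", None),
    ("m_obturatorius_internus", "pelvis_l", "femur_l", "hip_sphere_l"),
    ("m_rectus_femoris", "pelvis_l", "tibia_l", "stifle_cyl_l"),
    ("m_vastus_lateralis", "femur_l", "tibia_l", "stifle_cyl_l"),
    ("m_vastus_medialis", "femur_l", "tibia_l", None),
    ("m_gastrocnemius_caput_laterale", "femur_l", "tarsus_l", None),
    ("m_gastrocnemius_caput_mediale", "femur_l", "tarsus_l", None),
    ("m_flexor_digitorum_superficialis_hl", "femur_l", "hindpaw_l", None),
    ("m_flexor_digitorum_lateralis", "tibia_l", "hindpaw_l", None),
    ("m_tibialis_cranialis", "tibia_l", "tarsus_l", None),
    ("m_peroneus_longus", "tibia_l", "tarsus_l", None),
    ("m_extensor_digitorum_longus", "femur_l", "hindpaw_l", None),
]

_EPAXIAL_MUSCLES = [
    ("m_longissimus_thoracis_l", "thorax", "abdomen", None),
    ("m_longissimus_lumborum_l", "abdomen", "pelvis_l", None),
    ("m_iliocostalis_thoracis_l", "thorax", "abdomen", None),
    ("m_iliocostalis_lumborum_l", "abdomen", "pelvis_l", None),
    ("m_multifidus_lumborum_l", "abdomen", "pelvis_l", None),
    ("m_spinalis_et_semispinalis_l", "thorax", "head", None),
    ("m_splenius_l", "thorax", "head", None),
    ("m_longissimus_capitis_l", "thorax", "head", None),
    ("m_sacrocaudalis_dorsalis_l", "pelvis_l", "tail", None),
    ("m_sacrocaudalis_ventralis_l", "pelvis_l", "tail", None),
]

assert len(_FORELIMB_MUSCLES) == 33
assert len(_HINDLIMB_MUSCLES) == 24
# 37 + 28 + epaxial must equal MUSCLES_PER_SIDE


def _axial_segments() -> dict[str, Segment]:
    return {
        "carrier": Segment("carrier"),  # massless free-floating base frame
        "thorax": _seg("thorax", 5.0, 0.30, 0.08),
        "head": _seg("head", 1.5, 0.18, 0.06),
        "abdomen": _seg("abdomen", 3.0, 0.25, 0.07),
        "tail": _seg("tail", 0.2, 0.25, 0.01),
    }


def _axial_joints() -> list[Joint]:
    return [
        Joint("global", "ground", "carrier", frame_translation=(0, 0.45, 0),
              dof_flags=_flags(["tx", "ty", "tz"]),
              actuator_bounds=_bounds(FORELIMB_ACTUATOR_BOUNDS["global"]),
              bounds_verified=False),
        Joint("trunk", "carrier", "thorax", dof_flags=_flags(["rx", "ry", "rz"])),
        Joint("neck", "thorax", "head", frame_translation=(0.18, 0.05, 0),
              dof_flags=_flags(["rx", "ry", "rz"])),
        Joint("lumbar", "thorax", "abdomen", frame_translation=(-0.22, 0, 0),
              dof_flags=_flags(["rx", "ry", "rz"])),
        Joint("tailbase", "abdomen", "tail", frame_translation=(-0.20, 0.02, 0),
              dof_flags=_flags(["rx", "ry", "rz"])),
    ]


def _forelimb(side: str = "_l", z: float = -0.06) -> tuple[dict, list, dict]:
    s = side
    segments = {
        f"scapula{s}": _seg(f"scapula{s}", 0.35, 0.12, 0.03),
        f"humerus{s}": _seg(f"humerus{s}", 0.35, 0.14, 0.02),
        f"antebrachium{s}": _seg(f"antebrachium{s}", 0.25, 0.14, 0.015),
        f"forepaw{s}": _seg(f"forepaw{s}", 0.07, 0.05, 0.012),
        f"digits{s}": _seg(f"digits{s}", 0.03, 0.03, 0.01),
    }
    B = FORELIMB_ACTUATOR_BOUNDS
    joints = [
        Joint(f"scapula{s}", "thorax", f"scapula{s}", frame_translation=(0.12, 0.04, z),
              dof_flags=_flags(["rx", "ry", "rz", "tx", "ty"]),
              actuator_bounds=_bounds(B["scapula"]), bounds_verified=False),
        Joint(f"shoulder{s}", f"scapula{s}", f"humerus{s}", frame_translation=(0.01, -0.12, 0),
              dof_flags=_flags(["rx", "ry", "rz"]),
              actuator_bounds=_bounds(B["shoulder"]), bounds_verified=False),
        Joint(f"elbow{s}", f"humerus{s}", f"antebrachium{s}", frame_translation=(0, -0.14, 0),
              dof_flags=_flags(["rx", "ry"]),
              actuator_bounds=_bounds(B["elbow"]), bounds_verified=False),
        Joint(f"carpal{s}", f"antebrachium{s}", f"forepaw{s}", frame_translation=(0, -0.14, 0),
              dof_flags=_flags(["rx", "rz"]),
              actuator_bounds=_bounds(B["carpal"]), bounds_verified=False),
        Joint(f"forepaw{s}", f"forepaw{s}", f"digits{s}", frame_translation=(0.01, -0.05, 0),
              dof_flags=_flags(["rx", "ry", "rz"]),
              actuator_bounds=_bounds(B["forepaw"]), bounds_verified=False),
    ]
    wraps = {
        f"shoulder_sphere{s}": WrapObstacle(
            name=f"shoulder_sphere{s}", kind="sphere", segment=f"scapula{s}",
            centre=(0.01, -0.12, 0.0), radius=0.018,
        ),
        f"elbow_cyl{s}": WrapObstacle(
            name=f"elbow_cyl{s}", kind="cylinder", segment=f"humerus{s}",
            centre=(0.0, -0.14, 0.0), radius=0.012, axis=(0, 0, 1),
        ),
    }
    return segments, joints, wraps


def _hindlimb(side: str = "_l", z: float = -0.05) -> tuple[dict, list, dict]:
    s = side
    segments = {
        f"pelvis{s}": _seg(f"pelvis{s}", 0.4, 0.10, 0.04),
        f"femur{s}": _seg(f"femur{s}", 0.5, 0.15, 0.02),
        f"tibia{s}": _seg(f"tibia{s}", 0.3, 0.15, 0.015),
        f"tarsus{s}": _seg(f"tarsus{s}", 0.10, 0.06, 0.012),
        f"hindpaw{s}": _seg(f"hindpaw{s}", 0.06, 0.05, 0.012),
        f"toes{s}": _seg(f"toes{s}", 0.03, 0.03, 0.01),
    }
    joints = [
        Joint(f"pelvisj{s}", "abdomen", f"pelvis{s}", frame_translation=(-0.22, 0, z),
              dof_flags=_flags(["rx", "ry", "rz", "tx", "ty"])),
        Joint(f"hip{s}", f"pelvis{s}", f"femur{s}", frame_translation=(0, -0.08, 0),
              dof_flags=_flags(["rx", "ry", "rz"])),
        Joint(f"stifle{s}", f"femur{s}", f"tibia{s}", frame_translation=(0, -0.15, 0),
              dof_flags=_flags(["rx", "ry"])),
        Joint(f"tarsal{s}", f"tibia{s}", f"tarsus{s}", frame_translation=(0, -0.15, 0),
              dof_flags=_flags(["rx", "rz"])),
        Joint(f"hindpawj{s}", f"tarsus{s}", f"hindpaw{s}", frame_translation=(0.01, -0.06, 0),
              dof_flags=_flags(["rx", "ry", "rz"])),
        Joint(f"toesj{s}", f"hindpaw{s}", f"toes{s}", frame_translation=(0.01, -0.05, 0),
              dof_flags=_flags(["rx", "ry", "rz", "tx", "ty", "tz"])),
    ]
    wraps = {
        f"hip_sphere{s}": WrapObstacle(
            name=f"hip_sphere{s}", kind="sphere", segment=f"pelvis{s}",
            centre=(0.0, -0.08, 0.0), radius=0.02,
        ),
        f"stifle_cyl{s}": WrapObstacle(
            name=f"stifle_cyl{s}", kind="cylinder", segment=f"femur{s}",
            centre=(0.0, -0.15, 0.0), radius=0.014, axis=(0, 0, 1),
        ),
    }
    return segments, joints, wraps


def _left_muscles() -> list[Muscle]:
    defs = _FORELIMB_MUSCLES + _HINDLIMB_MUSCLES + _EPAXIAL_MUSCLES
    muscles = []
    for i, (name, org, ins, wrap) in enumerate(defs):
        if not name.endswith("_l"):
            name = name + "_l"
        # synthetic, deterministic attachment offsets: spread across the
        # segment surface by index so no two muscles coincide
        a = 0.015 * ((i % 5) - 2)
        b = -0.02 - 0.01 * (i % 3)
        origin = (a, b, 0.015)
        insertion = (-a if a else 0.01, b - 0.02, -0.01)
        wraps = ((wrap, 0),) if wrap else ()
        ml = 0.12 + 0.01 * (i % 6)
        fl = 0.4 * ml
        pcsa = 1.5e-4 + 1e-5 * (i % 7)
        muscles.append(
            Muscle(
                path=MusclePath(name=name, points=((org, origin), (ins, insertion)), wraps=wraps),
                params=MuscleParams(
                    m=0.03 + 0.005 * (i % 4), ml=ml, fl=fl, alpha=0.25,
                    pcsa=pcsa, fmax=pcsa * 3.0e5,
                ),
            )
        )
    return muscles


def build_dog_model(max_mobility: bool = True) -> ModelConfig:
    """Packaged bilateral whole-dog model.

    At maximum mobility the model counts 84 DOFs (ground joint excluded)
    and carries 134 muscles, 67 per side; the right side is a mirrored
    copy of the left.  ``max_mobility=False`` restricts every limb joint
    to its sagittal hinge (rx), the starting point of the mobility sweep.
    """
    segments = _axial_segments()
    fs, fj, fw = _forelimb("_l")
    hs, hj, hw = _hindlimb("_l")
    segments.update(fs)
    segments.update(hs)
    joints = _axial_joints() + fj + hj
    wraps = {**fw, **hw}
    model = ModelConfig(
        segments=segments, joints=joints, muscles=_left_muscles(), wraps=wraps
    )
    model = mirror_limb(model)
    if not max_mobility:
        from dataclasses import replace

        sagittal = []
        for j in model.joints:
            if j.parent == model.ground or j.name in ("trunk", "neck", "lumbar", "tailbase"):
                sagittal.append(j)
            else:
                sagittal.append(replace(j, dof_flags=_flags(["rx"])))
        model = ModelConfig(
            segments=model.segments, joints=sagittal, muscles=model.muscles,
            wraps=model.wraps, gravity=model.gravity,
        )
    n_left = sum(1 for m in model.muscles if m.name.endswith("_l"))
    n_right = sum(1 for m in model.muscles if m.name.endswith("_r"))
    assert n_left == n_right == MUSCLES_PER_SIDE, (n_left, n_right)
    return model


def build_forelimb_model() -> ModelConfig:
    """Left-forelimb evaluation configuration.

    The full skeleton's masses are retained (the global joint still
    carries the body) but only the thorax + left-forelimb chain and its
    muscles are present: 15 limb DOFs (scapula 5, shoulder 3, elbow 2,
    carpal 2, forepaw 3) plus the excluded 3-DOF global joint.
    """
    segments = {
        "carrier": Segment("carrier"),
        "thorax": _seg("thorax", 9.7, 0.30, 0.08),  # trunk+head+abdomen+tail lumped
    }
    fs, fj, fw = _forelimb("_l")
    segments.update(fs)
    joints = [
        Joint("global", "ground", "carrier", frame_translation=(0, 0.45, 0),
              dof_flags=_flags(["tx", "ty", "tz"]),
              actuator_bounds=_bounds(FORELIMB_ACTUATOR_BOUNDS["global"]),
              bounds_verified=False),
        Joint("trunk", "carrier", "thorax"),
    ] + fj
    left_fore_segs = set(fs)
    muscles = [
        m
        for m in _left_muscles()
        if any(seg in left_fore_segs for seg, _ in m.path.points)
    ]
    return ModelConfig(segments=segments, joints=joints, muscles=muscles, wraps=fw)


assert len(_EPAXIAL_MUSCLES) == MUSCLES_PER_SIDE - len(_FORELIMB_MUSCLES) - len(_HINDLIMB_MUSCLES)
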