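"""Synthetic fixtures and independent oracles.

Everything the pipeline needs to be exercised end-to-end without any
recorded data: pendulum chains with prescribed analytic motion (and an
independent Lagrangian torque oracle to validate the Newton–Euler
recursion), a three-segment toy limb with translational DOFs, a
biarticular muscle and a cylinder-wrapped muscle, planted-synergy
activation matrices with known group labels, and a plausible synthetic
walking trial (periodic joint angles plus a single-stance ground-reaction
pulse with a braking-then-propulsive fore-aft component).

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import GaitEvents, PoseSeries
from .inverse_dynamics import ExternalLoadSeries
from .model_core import (
    Joint,
    ModelConfig,
    Muscle,
    MuscleParams,
    MusclePath,
    Segment,
    WrapObstacle,
)

__all__ = [
    "PendulumSpec",
    "PlantedSynergySpec",
    "make_pendulum",
    "random_pendulum_spec",
    "lagrangian_torque_oracle",
    "make_toy_limb",
    "make_planted_activations",
    "make_archetype_activations",
    "make_synthetic_gait",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class PendulumSpec:
    """Chain of rigid links with prescribed sinusoidal joint motion.

    Each link extends along its local +x axis; link ``i`` hangs from the
    tip of link ``i-1``.  ``axes[i]`` is an ordered subset of ("x","y","z")
    — the enabled rotations of joint ``i`` in the intrinsic XYZ sequence.
    ``motion[i][axis] = (offset, amplitude, frequency_hz, phase)`` defines
    ``q(t) = offset + amplitude * sin(2 pi f t + phase)``.
    """

    masses: tuple[float, ...]
    lengths: tuple[float, ...]
    com_fracs: tuple[float, ...]
    axes: tuple[tuple[str, ...], ...]
    motion: tuple[dict, ...]
    inertias: tuple | None = None
    gravity: tuple[float, float, float] = (0.0, -9.81, 0.0)

    @property
    def n_links(self) -> int:
        return len(self.masses)

    def inertia(self, i: int) -> np.ndarray:
        if self.inertias is not None:
            return np.asarray(self.inertias[i], dtype=float)
        m, L = self.masses[i], self.lengths[i]
        return np.diag([1e-6, m * L * L / 12.0, m * L * L / 12.0])  # slender rod

    def coordinates(self) -> list[tuple[int, str]]:
        return [(i, ax) for i in range(self.n_links) for ax in self.axes[i]]

    def q_of_t(self, t: np.ndarray, deriv: int = 0) -> np.ndarray:
        """(n_samples, n_dofs) coordinate (or derivative) trajectories."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cols = []
        for i, ax in self.coordinates():
            off, amp, f, ph = self.motion[i][ax]
            w = 2 * np.pi * f
            if deriv == 0:
                cols.append(off + amp * np.sin(w * t + ph))
            elif deriv == 1:
                cols.append(amp * w * np.cos(w * t + ph))
            else:
                cols.append(-amp * w * w * np.sin(w * t + ph))
        return np.column_stack(cols)


def random_pendulum_spec(rng: np.random.Generator, n_links: int, planar: bool) -> PendulumSpec:
    """Random pendulum: planar chains rotate about z; 3D chains get one to
    three Cardan rotations per joint."""
    masses = tuple(rng.uniform(0.3, 3.0, n_links))
    lengths = tuple(rng.uniform(0.1, 0.6, n_links))
    com_fracs = tuple(rng.uniform(0.2, 0.8, n_links))
    axes = []
    motion = []
    for _ in range(n_links):
        if planar:
            ax = ("z",)
        else:
            choices = [("x",), ("y",), ("z",), ("x", "z"), ("x", "y", "z")]
            ax = choices[rng.integers(len(choices))]
        axes.append(ax)
        motion.append(
            {
                a: (
                    float(rng.uniform(-0.6, 0.6)),
                    float(rng.uniform(0.1, 0.7)),
                    float(rng.uniform(0.4, 1.6)),
                    float(rng.uniform(0, 2 * np.pi)),
                )
                for a in ax
            }
        )
    return PendulumSpec(
        masses=masses, lengths=lengths, com_fracs=com_fracs,
        axes=tuple(axes), motion=tuple(motion),
    )


def make_pendulum(spec: PendulumSpec, time: np.ndarray | None = None) -> tuple[ModelConfig, PoseSeries]:
    """Model plus pose series (with analytic derivatives) for a pendulum."""
    if time is None:
        time = np.linspace(0.0, 1.0, 51)
    segments = {}
    joints = []
    for i in range(spec.n_links):
        name = f"link{i}"
        L = spec.lengths[i]
        segments[name] = Segment(
            name=name,
            mass=spec.masses[i],
            com=np.array([spec.com_fracs[i] * L, 0.0, 0.0]),
            inertia=spec.inertia(i),
        )
        parent = "ground" if i == 0 else f"link{i - 1}"
        trans = np.zeros(3) if i == 0 else np.array([spec.lengths[i - 1], 0.0, 0.0])
        flags = [False] * 6
        for ax in spec.axes[i]:
            flags[_AXIS_INDEX[ax]] = True
        joints.append(
            Joint(
                name=f"joint{i}",
                parent=parent,
                child=name,
                frame_translation=trans,
                dof_flags=tuple(flags),
            )
        )
    model = ModelConfig(
        segments=segments, joints=joints, gravity=np.asarray(spec.gravity)
    )
    q = {f"joint{i}": np.zeros((time.size, 6)) for i in range(spec.n_links)}
    qd = {k: np.zeros_like(v) for k, v in q.items()}
    qdd = {k: np.zeros_like(v) for k, v in q.items()}
    Q0, Q1, Q2 = (spec.q_of_t(time, d) for d in (0, 1, 2))
    for k, (i, ax) in enumerate(spec.coordinates()):
        col = _AXIS_INDEX[ax]
        q[f"joint{i}"][:, col] = Q0[:, k]
        qd[f"joint{i}"][:, col] = Q1[:, k]
        qdd[f"joint{i}"][:, col] = Q2[:, k]
    pose = PoseSeries(time=time, q=q, qd=qd, qdd=qdd)
    return model, pose


# ---------------------------------------------------------------------------
# independent Lagrangian oracle


def _chain_kinematics(spec: PendulumSpec, q: np.ndarray):
    """Positions and orientations of every link for coordinate vector q.

    Deliberately written from scratch (supports complex dtype for
    derivative evaluation) — it shares no code with the Newton–Euler
    implementation beyond elementary trigonometry.
    """
    dtype = np.asarray(q).dtype
    coords = spec.coordinates()
    R = np.eye(3, dtype=dtype)
    o = np.zeros(3, dtype=dtype)
    out = []
    k = 0
    for i in range(spec.n_links):
        Ri = R.copy()
        for ax in spec.axes[i]:
            a = q[k]
            c, s = np.cos(a), np.sin(a)
            Rax = np.eye(3, dtype=dtype)
            if ax == "x":
                Rax[1, 1], Rax[1, 2], Rax[2, 1], Rax[2, 2] = c, -s, s, c
            elif ax == "y":
                Rax[0, 0], Rax[0, 2], Rax[2, 0], Rax[2, 2] = c, s, -s, c
            else:
                Rax[0, 0], Rax[0, 1], Rax[1, 0], Rax[1, 1] = c, -s, s, c
            Ri = Ri @ Rax
            k += 1
        com = np.array([spec.com_fracs[i] * spec.lengths[i], 0.0, 0.0], dtype=dtype)
        p_com = o + Ri @ com
        out.append((Ri, p_com))
        o = o + Ri @ np.array([spec.lengths[i], 0.0, 0.0], dtype=dtype)
        R = Ri
    assert k == len(coords)
    return out


_CSTEP = 1e-150


def _kinetic_energy(spec: PendulumSpec, q: np.ndarray, qd: np.ndarray) -> float:
    """T(q, qd) via a directional complex step: velocities are the exact
    directional derivatives of the position map along qd."""
    links0 = _chain_kinematics(spec, np.asarray(q, dtype=float))
    links1 = _chain_kinematics(spec, np.asarray(q, dtype=float) + 1j * _CSTEP * qd)
    T = 0.0
    for i, ((R0, _p0), (R1, p1)) in enumerate(zip(links0, links1)):
        v = np.imag(p1) / _CSTEP
        dR = np.imag(R1) / _CSTEP
        Wt = R0.T @ dR  # body-frame angular velocity, skew form
        w = np.array([Wt[2, 1], Wt[0, 2], Wt[1, 0]])
        T += 0.5 * spec.masses[i] * float(v @ v)
        T += 0.5 * float(w @ (spec.inertia(i) @ w))
    return T


def _potential_energy(spec: PendulumSpec, q: np.ndarray) -> float:
    g = np.asarray(spec.gravity, dtype=float)
    links = _chain_kinematics(spec, np.asarray(q, dtype=float))
    return -sum(spec.masses[i] * float(np.real(p) @ g) for i, (_, p) in enumerate(links))


def lagrangian_torque_oracle(
    spec: PendulumSpec,
    time: np.ndarray,
    dt: float = 1e-5,
    dq: float = 1e-6,
) -> np.ndarray:
    """Generalized joint torques of the prescribed motion, by Lagrange.

    ``tau_j = d/dt (dT/dqd_j) - dT/dq_j + dV/dq_j``.  The generalized
    momentum ``dT/dqd`` is evaluated exactly (kinetic energy is a
    quadratic form in the velocities), its time derivative by central
    differences of the prescribed trajectory at step ``dt``, and the
    configuration gradients by central differences at step ``dq``.

    Returns an ``(n_samples, n_dofs)`` array ordered like
    ``spec.coordinates()``.
    """
    time = np.atleast_1d(np.asarray(time, dtype=float))
    nd = len(spec.coordinates())

    def momentum(t: float) -> np.ndarray:
        qt = spec.q_of_t(np.array([t]))[0]
        qdt = spec.q_of_t(np.array([t]), 1)[0]
        p = np.zeros(nd)
        for j in range(nd):
            e = np.zeros(nd)
            e[j] = 1.0
            # T is quadratic in qd, so this central difference is exact
            p[j] = (
                _kinetic_energy(spec, qt, qdt + e) - _kinetic_energy(spec, qt, qdt - e)
            ) / 2.0
        return p

    out = np.zeros((time.size, nd))
    for s, t in enumerate(time):
        qt = spec.q_of_t(np.array([t]))[0]
        qdt = spec.q_of_t(np.array([t]), 1)[0]
        dp = (momentum(t + dt) - momentum(t - dt)) / (2 * dt)
        for j in range(nd):
            e = np.zeros(nd)
            e[j] = dq
            dTdq = (
                _kinetic_energy(spec, qt + e, qdt) - _kinetic_energy(spec, qt - e, qdt)
            ) / (2 * dq)
            dVdq = (
                _potential_energy(spec, qt + e) - _potential_energy(spec, qt - e)
            ) / (2 * dq)
            out[s, j] = dp[j] - dTdq + dVdq
    return out


# ---------------------------------------------------------------------------
# toy limb


def make_toy_limb(seed: int = 0) -> ModelConfig:
    """Deterministic three-segment limb exercising the full model surface.

    A trunk fixed to ground carries a scapula-analog segment on a joint
    with translational anterior-posterior/vertical DOFs plus a hinge — the
    mobility a muscle-slung shoulder girdle needs — then hinge shoulder
    and elbow analogs.  Eight muscles include antagonist pairs about every
    DOF, one biarticular muscle spanning shoulder and elbow, and one
    muscle wrapped over a cylinder coaxial with the elbow hinge.
    """
    rng = np.random.default_rng(seed)
    segments = {
        "trunk": Segment("trunk", mass=8.0, com=(0, 0, 0), inertia=np.diag([0.1, 0.1, 0.1])),
        "scap": Segment("scap", mass=0.4, com=(0.0, -0.03, 0.0), inertia=np.diag([4e-4, 4e-4, 4e-4])),
        "upper": Segment("upper", mass=0.5, com=(0.0, -0.06, 0.0), inertia=np.diag([6e-4, 1e-4, 6e-4])),
        "lower": Segment("lower", mass=0.3, com=(0.0, -0.05, 0.0), inertia=np.diag([3e-4, 5e-5, 3e-4])),
    }
    joints = [
        Joint("root", "ground", "trunk", frame_translation=(0, 0.4, 0)),
        Joint(
            "scapj", "trunk", "scap",
            frame_translation=(0.0, -0.05, 0.05),
            dof_flags=(False, False, True, True, True, False),  # rz + tx + ty
        ),
        Joint(
            "shoulder", "scap", "upper",
            frame_translation=(0.0, -0.06, 0.0),
            dof_flags=(False, False, True, False, False, False),
        ),
        Joint(
            "elbow", "upper", "lower",
            frame_translation=(0.0, -0.12, 0.0),
            dof_flags=(False, False, True, False, False, False),
        ),
    ]
    wraps = {
        "elbow_cyl": WrapObstacle(
            name="elbow_cyl", kind="cylinder", segment="upper",
            centre=(0.0, -0.12, 0.0), radius=0.015, axis=(0, 0, 1),
        )
    }

    def mus(name, points, wraps_=(), fmax=300.0):
        return (name, points, wraps_, fmax)

    defs = [
        # scapular sling: antagonists along x (protraction/retraction)
        mus("protractor_sling", [("trunk", (0.10, -0.02, 0.05)), ("scap", (0.01, -0.02, 0.0))]),
        mus("retractor_sling", [("trunk", (-0.10, -0.02, 0.05)), ("scap", (-0.01, -0.02, 0.0))]),
        # vertical suspension (up) and a depressor pair (down; their fore-aft
        # components cancel so the pair can bear the stance load vertically)
        mus("serratus_analog", [("trunk", (0.0, 0.02, 0.05)), ("scap", (0.0, -0.05, 0.0))]),
        mus("depressor_cranialis", [("trunk", (0.06, -0.12, 0.05)), ("scap", (0.02, -0.06, 0.0))], fmax=500.0),
        mus("depressor_caudalis", [("trunk", (-0.06, -0.12, 0.05)), ("scap", (-0.02, -0.06, 0.0))], fmax=500.0),
        # shoulder hinge: flexor; extension is carried by the biarticular
        mus("shoulder_flexor", [("scap", (0.03, -0.04, 0.0)), ("upper", (0.02, -0.05, 0.0))]),
        # biarticular: extends shoulder and elbow
        mus("biarticular_extensor", [("scap", (-0.025, -0.05, 0.0)), ("lower", (-0.02, -0.03, 0.0))]),
        # wrapped elbow flexor over the cylinder at the elbow
        mus(
            "wrapped_elbow_flexor",
            [("upper", (0.025, -0.02, 0.0)), ("lower", (0.02, -0.04, 0.0))],
            wraps_=(("elbow_cyl", 0),),
        ),
    ]
    muscles = []
    for name, pts, wr, fmax in defs:
        path = MusclePath(name=name, points=tuple((s, np.array(p)) for s, p in pts), wraps=tuple(wr))
        # fibre sized to the default-pose path length: fully fleshed, no tendon
        muscles.append(
            Muscle(
                path=path,
                params=MuscleParams(
                    m=0.05, ml=0.2, fl=0.2, alpha=0.0, pcsa=fmax / 3.0e5,
                    fmax=fmax, tl=0.0, tendon_slack=0.0,
                ),
            )
        )
    model = ModelConfig(segments=segments, joints=joints, muscles=muscles, wraps=wraps)
    # freeze fibre lengths at the default-pose path lengths so the
    # force-length curve sits near its optimum in the working range
    from .muscle_mechanics import path_length

    sized = []
    for m in model.muscles:
        L0 = path_length(model, m).length
        sized.append(
            Muscle(path=m.path, params=MuscleParams(
                m=m.params.m, ml=L0, fl=L0, alpha=0.0, pcsa=m.params.pcsa,
                fmax=m.params.fmax, tl=0.0, tendon_slack=0.0,
            ))
        )
    model.muscles = sized
    return model


# ---------------------------------------------------------------------------
# planted synergies


@dataclass(frozen=True)
class PlantedSynergySpec:
    """Planted-partition activation design: known groups plus noise.

    ``n_main`` motif families × ``n_sub`` variants × ``muscles_per_sub``
    muscles; additive Gaussian noise (sd ``sigma``) is applied before
    clipping to [0, 1], so clipping at zero creates the zero-activation
    mass the log-flooring must handle.
    """

    n_main: int = 3
    n_sub: int = 2
    muscles_per_sub: int = 4
    sigma: float = 0.05
    seed: int = 0
    n_points: int = 101
    stance_fraction: float = 0.6

    @property
    def n_muscles(self) -> int:
        return self.n_main * self.n_sub * self.muscles_per_sub


def _bump(t: np.ndarray, centre: float, width: float) -> np.ndarray:
    """Periodic Gaussian bump on the unit stride."""
    out = np.zeros_like(t)
    for k in (-1.0, 0.0, 1.0):
        out += np.exp(-0.5 * ((t - centre + k) / width) ** 2)
    return out


def _smooth_box(t: np.ndarray, lo: float, hi: float, sharp: float = 0.02) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - lo) / sharp)) - 1.0 / (1.0 + np.exp(-(t - hi) / sharp))


def planted_motif(main: int, sub: int, t: np.ndarray, stance: float = 0.6) -> np.ndarray:
    """Activation motif of a (main group, subgroup) pair on the unit stride.

    The stride is split into six phase windows — early/mid/late stance and
    early/mid/late swing — and each motif family is active (0.85) in two
    consecutive windows, silent down to a 0.2 baseline elsewhere: family 0
    through early-mid stance (extensor-like), family 1 across the late
    stance / early swing transition, family 2 through mid-late swing
    (protractor-like).  Subgroup 0 fills both windows; subgroup 1 only the
    first.  Every family pair then differs over the same number of
    samples, so the three families sit at (log-space) equal mutual
    distances — the planted analogue of three synergy groups hanging at
    the same length from the dendrogram root — while subgroup splits are
    strictly tighter than family splits.  The 0.2 baseline keeps clean
    motifs away from the log floor; noise clipping at zero is what the
    floor must absorb.
    """
    base, high = 0.2, 0.85
    thirds = [
        (0.0, stance / 3),
        (stance / 3, 2 * stance / 3),
        (2 * stance / 3, stance),
        (stance, stance + (1 - stance) / 3),
        (stance + (1 - stance) / 3, stance + 2 * (1 - stance) / 3),
        (stance + 2 * (1 - stance) / 3, 1.0),
    ]

    def window(k: int) -> np.ndarray:
        lo, hi = thirds[k]
        return _smooth_box(t, lo + 0.01, hi - 0.01, sharp=0.015)

    out = base + (high - base) * window(2 * main)
    if sub == 0:
        out = out + (high - base) * window(2 * main + 1)
    return np.clip(out, 0.0, 1.0)


def make_planted_activations(spec: PlantedSynergySpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Activation matrix with planted group structure.

    Returns ``(A, main_labels, sub_labels)``; ``A`` is
    ``(n_muscles, n_points)`` in [0, 1], rows grouped by (main, sub).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, 1.0, spec.n_points)
    rows, main_lab, sub_lab = [], [], []
    for g in range(spec.n_main):
        for s in range(spec.n_sub):
            motif = planted_motif(g, s, t, spec.stance_fraction)
            for _ in range(spec.muscles_per_sub):
                noisy = motif + rng.normal(0.0, spec.sigma, t.size)
                rows.append(np.clip(noisy, 0.0, 1.0))
                main_lab.append(g)
                sub_lab.append(g * spec.n_sub + s)
    return np.array(rows), np.array(main_lab), np.array(sub_lab)


def make_archetype_activations(
    n_points: int = 101, stance: float = 0.6, n_serratus: int = 4, sigma: float = 0.02, seed: int = 0
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Qualitative walking archetypes: stance extensors, swing protractors,
    and a cranial-to-caudal travelling activation wave across serratus
    slips around touchdown and toe-off.

    Returns ``(A, names, stance_dominated)`` where the boolean marks
    muscles whose activation mass lies in stance.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_points)
    rows, names = [], []
    for k in range(3):
        rows.append(0.2 + 0.6 * _smooth_box(t, 0.03, stance - 0.03))
        names.append(f"stance_extensor_{k}")
    for k in range(3):
        rows.append(0.2 + 0.6 * _bump(t, stance + 0.12 + 0.06 * k, 0.06))
        names.append(f"swing_protractor_{k}")
    for k in range(n_serratus):  # wave travels cranial -> caudal
        shift = 0.04 * k
        rows.append(
            0.2 + 0.45 * _bump(t, 0.0 + shift, 0.05) + 0.45 * _bump(t, stance + shift, 0.05)
        )
        names.append(f"serratus_slip_{k}")
    A = np.clip(np.array(rows) + rng.normal(0, sigma, (len(rows), n_points)), 0, 1)
    stance_mask = t < stance
    dominated = np.array([row[stance_mask].sum() > row[~stance_mask].sum() for row in A])
    return A, names, dominated


# ---------------------------------------------------------------------------
# synthetic gait


def make_synthetic_gait(
    model: ModelConfig,
    seed: int = 0,
    paw_segment: str | None = None,
    n_points: int = 101,
    stride_time: float = 0.5,
    duty: float = 0.6,
    weight_fraction: float = 0.3,
) -> tuple[PoseSeries, ExternalLoadSeries]:
    """Stride-periodic joint kinematics plus a plausible GRF.

    Every enabled DOF oscillates sinusoidally at the stride frequency
    (rotations ±~0.15 rad, translations ±~8 mm), so the first and last
    frames coincide and derivatives are analytic.  The vertical GRF is a
    single-stance half-sine-squared pulse whose impulse equals
    ``weight_fraction`` of body weight × stride time; the fore-aft
    component brakes through early stance and propels in late stance; the
    load is zero throughout swing.  The centre of pressure tracks under
    the paw segment.
    """
    if paw_segment is None:
        children = model.children()
        seg = model.ground
        while children.get(seg):
            seg = children[seg][0].child
        paw_segment = seg
    rng = np.random.default_rng(seed)
    time = np.linspace(0.0, stride_time, n_points)
    w = 2 * np.pi / stride_time
    q, qd, qdd = {}, {}, {}
    for j in model.joint_order():
        qj = np.zeros((n_points, 6))
        qdj = np.zeros((n_points, 6))
        qddj = np.zeros((n_points, 6))
        for k in j.enabled():
            amp = rng.uniform(0.08, 0.2) if k < 3 else rng.uniform(0.004, 0.01)
            off = rng.uniform(-0.1, 0.1) if k < 3 else rng.uniform(-0.005, 0.005)
            ph = rng.uniform(0, 2 * np.pi)
            qj[:, k] = off + amp * np.sin(w * time + ph)
            qdj[:, k] = amp * w * np.cos(w * time + ph)
            qddj[:, k] = -amp * w * w * np.sin(w * time + ph)
        q[j.name], qd[j.name], qdd[j.name] = qj, qdj, qddj
    events = GaitEvents(
        touchdown=0, toeoff=int(round(duty * (n_points - 1))), next_touchdown=n_points - 1
    )
    pose = PoseSeries(time=time, q=q, qd=qd, qdd=qdd, events=events)

    total_mass = sum(s.mass for s in model.segments.values())
    g_mag = float(np.linalg.norm(model.gravity))
    amp_f = 2.0 * weight_fraction * total_mass * g_mag / duty
    s = time / stride_time
    stance = s < duty
    fy = np.where(stance, amp_f * np.sin(np.pi * np.minimum(s / duty, 1.0)) ** 2, 0.0)
    fx = np.where(stance, -0.2 * amp_f * np.sin(2 * np.pi * np.minimum(s / duty, 1.0)), 0.0)
    force = np.column_stack([fx, fy, np.zeros_like(fy)])
    cop = np.zeros((n_points, 3))
    for i in range(n_points):
        qi, _, _ = pose.frame(i)
        fk = model.forward_kinematics(qi)
        o = fk[paw_segment][1]
        cop[i] = [o[0] + 0.02 * (s[i] / duty - 0.5), 0.0, o[2]]
    return pose, ExternalLoadSeries(applied_segment=paw_segment, force=force, cop=cop)
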