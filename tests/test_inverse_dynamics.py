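"""Newton-Euler recursion against independent dynamics oracles."""

import numpy as np
import pytest

from caninemsk.inverse_dynamics import (
    apply_sign_convention,
    express_in_joint_frames,
    generalized_forces,
    newton_euler,
)
from caninemsk.kinematics import PoseSeries, cardan_matrix
from caninemsk.synthetic import (
    PendulumSpec,
    lagrangian_torque_oracle,
    make_pendulum,
    random_pendulum_spec,
)


def _static_link(angle_offset: float) -> tuple:
    spec = PendulumSpec(
        masses=(1.0,), lengths=(0.2,), com_fracs=(0.5,), axes=(("z",),),
        motion=({"z": (angle_offset, 0.0, 1.0, 0.0)},),
    )
    return make_pendulum(spec, time=np.linspace(0, 0.1, 3))


def _oracle_columns(spec, gen):
    ax_idx = {"x": 0, "y": 1, "z": 2}
    return np.column_stack(
        [gen[(f"joint{i}", ax_idx[ax])] for i, ax in spec.coordinates()]
    )


class TestStaticCases:
    def test_horizontal_link_gravitational_moment(self):
        """m=1 kg at d=0.1 m horizontally: joint moment 0.981 Nm."""
        model, pose = _static_link(0.0)
        torques = newton_euler(model, pose)
        assert np.linalg.norm(torques.moment["joint0"][0]) == pytest.approx(0.981, abs=1e-9)

    def test_vertical_link_zero_moment(self):
        model, pose = _static_link(-np.pi / 2)  # com straight below the joint
        torques = newton_euler(model, pose)
        assert np.linalg.norm(torques.moment["joint0"][0]) <= 1e-12

    def test_static_pose_zero_grf_is_pure_gravity(self):
        """At rest the moment equals m g d cos(angle) for every offset."""
        for ang in (0.3, -0.7, 1.2):
            model, pose = _static_link(ang)
            torques = newton_euler(model, pose)
            expected = 1.0 * 9.81 * 0.1 * np.cos(ang)
            assert torques.moment["joint0"][0][2] == pytest.approx(expected, abs=1e-9)


def _double_pendulum_closed_form(spec, t):
    """Hand-coded classic planar double-pendulum equations of motion.

    Point-mass-free form with distal rod inertia about the com:
    tau = M(q) qdd + C(q, qd) + G(q), derived once symbolically and
    committed as code.  Angles are absolute link angles measured from the
    +x axis (the chain's joint coordinates are theta1 and theta2-theta1
    relative; here both joints rotate about z so q2 is relative).
    """
    m1, m2 = spec.masses
    L1, L2 = spec.lengths
    c1 = spec.com_fracs[0] * L1
    c2 = spec.com_fracs[1] * L2
    I1 = spec.inertia(0)[2, 2]
    I2 = spec.inertia(1)[2, 2]
    g = 9.81
    q = spec.q_of_t(t)
    qd = spec.q_of_t(t, 1)
    qdd = spec.q_of_t(t, 2)
    th1, th2 = q[:, 0], q[:, 1]
    w1, w2 = qd[:, 0], qd[:, 1]
    a1, a2 = qdd[:, 0], qdd[:, 1]
    # mass matrix (q2 relative to link 1)
    M11 = I1 + I2 + m1 * c1**2 + m2 * (L1**2 + c2**2 + 2 * L1 * c2 * np.cos(th2))
    M12 = I2 + m2 * (c2**2 + L1 * c2 * np.cos(th2))
    M22 = I2 + m2 * c2**2
    h = m2 * L1 * c2 * np.sin(th2)
    C1 = -h * (2 * w1 * w2 + w2**2)
    C2 = h * w1**2
    G1 = (m1 * c1 + m2 * L1) * g * np.cos(th1) + m2 * c2 * g * np.cos(th1 + th2)
    G2 = m2 * c2 * g * np.cos(th1 + th2)
    tau1 = M11 * a1 + M12 * a2 + C1 + G1
    tau2 = M12 * a1 + M22 * a2 + C2 + G2
    return np.column_stack([tau1, tau2])


class TestOracleAgreement:
    def test_planar_double_pendulum_closed_form(self):
        """Match the hand-derived double-pendulum equations of motion."""
        spec = PendulumSpec(
            masses=(1.2, 0.7), lengths=(0.3, 0.25), com_fracs=(0.45, 0.6),
            axes=(("z",), ("z",)),
            motion=(
                {"z": (0.2, 0.5, 0.9, 0.3)},
                {"z": (-0.4, 0.6, 1.3, 1.1)},
            ),
        )
        # gravity along -y: closed form uses cos(theta) moments about z
        t = np.linspace(0, 1, 31)
        model, pose = make_pendulum(spec, time=t)
        gen = generalized_forces(newton_euler(model, pose), model, pose)
        got = _oracle_columns(spec, gen)
        expected = _double_pendulum_closed_form(spec, t)
        scale = np.max(np.abs(expected))
        assert np.max(np.abs(got - expected)) <= 1e-9 * max(scale, 1.0)

    @pytest.mark.parametrize("n_links,planar", [(1, True), (2, True), (3, True),
                                                (1, False), (2, False), (3, False)])
    def test_random_chains_match_numeric_lagrangian(self, n_links, planar, rng):
        for _ in range(4):
            spec = random_pendulum_spec(rng, n_links, planar)
            t = np.linspace(0, 1, 9)
            model, pose = make_pendulum(spec, time=t)
            gen = generalized_forces(newton_euler(model, pose), model, pose)
            got = _oracle_columns(spec, gen)
            expected = lagrangian_torque_oracle(spec, t)
            scale = max(np.max(np.abs(expected)), 1e-3)
            assert np.max(np.abs(got - expected)) <= 1e-6 * scale

    def test_zero_gravity_spinning_link_pure_inertia(self):
        """Without gravity, a link spun about its axis needs I*alpha."""
        spec = PendulumSpec(
            masses=(2.0,), lengths=(0.3,), com_fracs=(0.0,), axes=(("z",),),
            motion=({"z": (0.0, 0.8, 1.0, 0.0)},), gravity=(0.0, 0.0, 0.0),
        )
        t = np.linspace(0, 1, 11)
        model, pose = make_pendulum(spec, time=t)
        torques = newton_euler(model, pose)
        I_zz = spec.inertia(0)[2, 2]
        alpha = spec.q_of_t(t, 2)[:, 0]
        assert np.allclose(torques.moment["joint0"][:, 2], I_zz * alpha, atol=1e-12)


class TestGlobalConsistency:
    def test_energy_balance_conservative_motion(self):
        """Integrated joint power equals the change in mechanical energy."""
        spec = PendulumSpec(
            masses=(1.0, 0.5), lengths=(0.3, 0.2), com_fracs=(0.5, 0.5),
            axes=(("z",), ("z",)),
            motion=({"z": (0.1, 0.4, 1.0, 0.0)}, {"z": (0.3, 0.5, 1.0, 0.7)}),
        )
        t = np.linspace(0, 0.8, 801)
        model, pose = make_pendulum(spec, time=t)
        gen = generalized_forces(newton_euler(model, pose), model, pose)
        qd = spec.q_of_t(t, 1)
        power = gen[("joint0", 2)] * qd[:, 0] + gen[("joint1", 2)] * qd[:, 1]
        work = np.trapezoid(power, t)
        from caninemsk.synthetic import _kinetic_energy, _potential_energy

        def energy(tt):
            q = spec.q_of_t(np.array([tt]))[0]
            v = spec.q_of_t(np.array([tt]), 1)[0]
            return _kinetic_energy(spec, q, v) + _potential_energy(spec, q)

        dE = energy(t[-1]) - energy(t[0])
        assert work == pytest.approx(dE, rel=1e-4, abs=1e-6)

    def test_root_force_equals_total_mass_times_com_acceleration(self, rng):
        """Whole-body check: the ground reaction (root joint force) matches
        total mass x (COM acceleration - g)."""
        spec = random_pendulum_spec(rng, 2, planar=False)
        t = np.linspace(0.1, 0.9, 7)
        model, pose = make_pendulum(spec, time=t)
        torques = newton_euler(model, pose)
        from caninemsk.synthetic import _chain_kinematics

        def com(tt):
            q = spec.q_of_t(np.array([tt]))[0]
            links = _chain_kinematics(spec, q)
            return sum(spec.masses[i] * p for i, (_, p) in enumerate(links))

        total_mass = sum(spec.masses)
        g = np.array([0.0, -9.81, 0.0])
        for k, tt in enumerate(t):
            h = 1e-3
            acc = (
                -com(tt + 2 * h) + 16 * com(tt + h) - 30 * com(tt)
                + 16 * com(tt - h) - com(tt - 2 * h)
            ) / (12 * h * h)
            # com() is the mass-weighted position sum, so acc is the total
            # inertial force; subtracting total weight gives the root force
            expected = acc - total_mass * g
            assert np.max(np.abs(torques.force["joint0"][k] - expected)) <= 1e-6


class TestFrameHandling:
    def test_identity_orientation_unchanged(self):
        model, pose = _static_link(0.0)
        lab = newton_euler(model, pose)
        joint = express_in_joint_frames(lab, model, pose)
        assert np.allclose(joint.moment["joint0"], lab.moment["joint0"])

    def test_quarter_turn_swaps_components(self):
        model, pose = _static_link(0.0)
        lab = newton_euler(model, pose)
        lab.moment["joint0"][:] = [1.0, 0.0, 0.0]
        pose_rot = PoseSeries(
            time=pose.time,
            q={"joint0": np.tile([0, 0, np.pi / 2, 0, 0, 0], (3, 1)).astype(float)},
            qd={"joint0": np.zeros((3, 6))},
            qdd={"joint0": np.zeros((3, 6))},
        )
        joint = express_in_joint_frames(lab, model, pose_rot)
        assert np.allclose(joint.moment["joint0"][0], [0.0, -1.0, 0.0], atol=1e-12)

    def test_random_orientation_matches_rotation_oracle(self, rng):
        model, pose = _static_link(0.0)
        angles = rng.uniform(-1, 1, 3)
        qmat = np.tile(np.concatenate([angles, np.zeros(3)]), (3, 1))
        pose_rot = PoseSeries(
            time=pose.time, q={"joint0": qmat},
            qd={"joint0": np.zeros((3, 6))}, qdd={"joint0": np.zeros((3, 6))},
        )
        lab = newton_euler(model, pose_rot)
        joint = express_in_joint_frames(lab, model, pose_rot)
        R = cardan_matrix(*angles)
        assert np.max(np.abs(joint.moment["joint0"][0] - R.T @ lab.moment["joint0"][0])) <= 1e-12


class TestSignConvention:
    def _series(self, value):
        model, pose = _static_link(0.0)
        t = newton_euler(model, pose)
        t = express_in_joint_frames(t, model, pose)
        for name in t.moment:
            t.moment[name][:] = value
        return t

    def test_zero_is_zero(self):
        t = apply_sign_convention(self._series([0.0, 0.0, 0.0]), {"joint0": [-1, 1, 1]})
        assert np.allclose(t.moment["joint0"], 0.0)

    def test_elbow_extension_flips_to_retractor_positive(self):
        t = self._series([1.0, 0.0, 0.0])
        out = apply_sign_convention(t, {"joint0": np.array([-1.0, 1.0, 1.0])})
        assert np.allclose(out.moment["joint0"][:, 0], -1.0)

    def test_applying_twice_is_identity(self):
        t = self._series([1.0, -2.0, 0.5])
        conv = {"joint0": np.array([-1.0, 1.0, -1.0])}
        twice = apply_sign_convention(apply_sign_convention(t, conv), conv)
        assert np.allclose(twice.moment["joint0"], t.moment["joint0"])

    def test_unregistered_joint_keeps_raw_signs(self):
        t = self._series([1.0, -2.0, 0.5])
        out = apply_sign_convention(t, {})
        assert np.allclose(out.moment["joint0"], t.moment["joint0"])
        assert np.allclose(out.sign_convention["joint0"], 1.0)


class TestPreconditions:
    def test_missing_derivatives_rejected(self):
        model, pose = _static_link(0.0)
        bare = PoseSeries(time=pose.time, q=pose.q)
        with pytest.raises(ValueError, match="velocity"):
            newton_euler(model, bare)

    def test_load_on_unknown_segment_rejected(self):
        from caninemsk.inverse_dynamics import ExternalLoadSeries

        model, pose = _static_link(0.0)
        load = ExternalLoadSeries(
            applied_segment="nope", force=np.zeros((3, 3)), cop=np.zeros((3, 3))
        )
        with pytest.raises(KeyError):
            newton_euler(model, pose, load)
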