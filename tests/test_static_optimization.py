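"""Frame QP, trial solver, actuator-bound scan, and DOF sweep."""

import numpy as np
import pytest

from caninemsk.inverse_dynamics import TorqueSeries, newton_euler
from caninemsk.kinematics import PoseSeries
from caninemsk.model_core import (
    Joint,
    ModelConfig,
    Muscle,
    MuscleParams,
    MusclePath,
    Segment,
)
from caninemsk.static_optimization import (
    dof_sweep,
    scan_actuator_bounds,
    solve_frame,
    solve_trial,
)


class TestSolveFrame:
    def test_single_muscle_canonical(self):
        """a = tau / (r * fmax) = 1 / (0.02 * 100) = 0.5, reserve ~ 0."""
        s = solve_frame(np.array([1.0]), np.array([[0.02]]), np.array([100.0]), np.array([10.0]))
        assert s.status == "ok"
        assert s.activations[0] == pytest.approx(0.5, abs=1e-8)
        assert abs(s.reserves[0]) <= 1e-8

    def test_two_identical_muscles_split_equally(self):
        s = solve_frame(
            np.array([1.0]), np.array([[0.02], [0.02]]),
            np.array([100.0, 100.0]), np.array([10.0]),
        )
        assert np.allclose(s.activations, 0.25, atol=1e-8)

    def test_three_muscle_closed_form_and_brute_force(self):
        """Interior optimum a_i = tau k_i / sum(k^2); grid search agrees."""
        gains = np.array([100.0, 150.0, 80.0])
        r = 0.02
        k = r * gains
        tau = np.array([1.5])
        s = solve_frame(tau, np.full((3, 1), r), gains, np.array([50.0]))
        expected = tau[0] * k / (k @ k)
        assert np.allclose(s.activations, expected, atol=1e-7)
        # brute force: a1, a2 on a 1e-3 grid, a3 from the torque balance
        a1, a2 = np.meshgrid(np.arange(0, 1.0005, 1e-3), np.arange(0, 1.0005, 1e-3))
        a3 = (tau[0] - k[0] * a1 - k[1] * a2) / k[2]
        valid = (a3 >= 0) & (a3 <= 1)
        obj = np.where(valid, a1**2 + a2**2 + a3**2, np.inf)
        assert s.objective <= obj.min() + 1e-5

    def test_beats_random_feasible_points(self, rng):
        gains = np.array([120.0, 60.0, 200.0, 90.0])
        R = rng.uniform(-0.05, 0.05, (4, 2))
        tau = R.T @ (gains * np.array([0.3, 0.5, 0.2, 0.4]))
        s = solve_frame(tau, R, gains, np.array([1e-6, 1e-6]))
        assert s.status == "ok"
        # random feasible activations: solve the 2 equality constraints for
        # two muscles given random values of the other two
        count = 0
        A = R.T * gains
        for _ in range(3000):
            if count >= 1000:
                break
            free = rng.uniform(0, 1, 2)
            sub = A[:, 2:]
            rest = tau - A[:, :2] @ free
            try:
                pinned = np.linalg.solve(sub, rest)
            except np.linalg.LinAlgError:
                continue
            a = np.concatenate([free, pinned])
            if np.all((a >= 0) & (a <= 1)):
                count += 1
                assert s.objective <= a @ a + 1e-9
        assert count >= 1000

    def test_infeasible_reported_not_raised(self):
        s = solve_frame(np.array([5.0]), np.array([[0.02]]), np.array([100.0]), np.array([0.5]))
        assert s.status == "infeasible"

    def test_muscles_preferred_over_reserves(self):
        """Reserves stay at the minimum the muscles cannot cover."""
        s = solve_frame(np.array([4.0]), np.array([[0.02]]), np.array([100.0]), np.array([50.0]))
        assert s.activations[0] == pytest.approx(1.0, abs=1e-8)
        assert s.reserves[0] == pytest.approx(2.0, abs=1e-6)

    def test_passive_force_moved_to_rhs(self):
        s = solve_frame(
            np.array([1.0]), np.array([[0.02]]), np.array([100.0]),
            np.array([10.0]), passive=np.array([25.0]),
        )
        # passive torque 0.5 Nm; muscles cover the remaining 0.5
        assert s.activations[0] == pytest.approx(0.25, abs=1e-8)


def _hinge_muscle_model(fmax=100.0, n_muscles=1):
    segments = {"base": Segment("base"), "a": Segment("a", 0.0, inertia=np.zeros(3))}
    joints = [
        Joint("root", "ground", "base"),
        Joint("j", "base", "a", dof_flags=(False, False, True, False, False, False)),
    ]
    muscles = []
    for i in range(n_muscles):
        muscles.append(
            Muscle(
                path=MusclePath(f"m{i}", (("base", (0.02, 0.1, 0.0)), ("a", (0.02, -0.1, 0.0)))),
                params=MuscleParams(ml=0.2, fl=0.2, alpha=0.0, fmax=fmax,
                                    pcsa=fmax / 3e5, tendon_slack=0.0),
            )
        )
    return ModelConfig(segments=segments, joints=joints, muscles=muscles)


def _constant_torque_series(model, pose, tau_z):
    n = pose.n_samples
    moment = {j.name: np.tile([0.0, 0.0, tau_z], (n, 1)) for j in model.joints}
    force = {j.name: np.zeros((n, 3)) for j in model.joints}
    return TorqueSeries(time=pose.time, moment=moment, force=force, frame="lab")


def _static_pose(model, n=3):
    t = np.linspace(0, 1, n)
    q = {j.name: np.zeros((n, 6)) for j in model.joints}
    zeros = {j.name: np.zeros((n, 6)) for j in model.joints}
    return PoseSeries(time=t, q=q, qd=zeros, qdd={k: v.copy() for k, v in zeros.items()})


class TestSolveTrial:
    def test_zero_torque_zero_activation(self, toy_limb, toy_gait):
        pose, _ = toy_gait
        n = pose.n_samples
        zero = TorqueSeries(
            time=pose.time,
            moment={j.name: np.zeros((n, 3)) for j in toy_limb.joints},
            force={j.name: np.zeros((n, 3)) for j in toy_limb.joints},
        )
        act = solve_trial(toy_limb, pose, zero, bound_override=1e-9, include_passive=False)
        # pose matters only through moment arms here; hold it at reference
        static = _static_pose(toy_limb, n=n)
        act = solve_trial(toy_limb, static, zero, bound_override=1e-9, include_passive=False)
        assert act.converged
        assert np.max(np.abs(act.a)) <= 1e-8

    def test_constant_torque_constant_activation(self):
        model = _hinge_muscle_model()
        pose = _static_pose(model, n=4)
        torques = _constant_torque_series(model, pose, 1.0)
        act = solve_trial(model, pose, torques, bound_override=10.0, include_passive=False)
        assert act.converged
        assert np.allclose(act.a, act.a[:, :1], atol=1e-9)
        assert np.allclose(act.a[0], 0.5, atol=1e-8)  # r=0.02, fmax=100

    def test_warm_start_changes_speed_not_solution(self, toy_limb, toy_gait, toy_torques):
        pose, _ = toy_gait
        warm = solve_trial(toy_limb, pose, toy_torques, bound_override=200.0)
        cold = solve_trial(toy_limb, pose, toy_torques, bound_override=200.0, warm_start=False)
        assert warm.converged and cold.converged
        assert np.max(np.abs(warm.objective - cold.objective)) <= 1e-8

    def test_infeasible_frames_reported_partially(self, toy_limb, toy_gait, toy_torques):
        pose, _ = toy_gait
        act = solve_trial(toy_limb, pose, toy_torques, bound_override=1e-9)
        assert not act.converged
        assert 0 < len(act.failed_frames) < pose.n_samples

    def test_reserves_vanish_as_capacity_grows(self, toy_limb, toy_gait, toy_torques):
        pose, _ = toy_gait
        from dataclasses import replace

        usages = []
        for scale in (1.0, 10.0, 100.0):
            model = ModelConfig(
                segments=dict(toy_limb.segments),
                joints=list(toy_limb.joints),
                muscles=[
                    Muscle(m.path, replace(m.params, fmax=m.params.fmax * scale,
                                            pcsa=m.params.pcsa * scale))
                    for m in toy_limb.muscles
                ],
                wraps=dict(toy_limb.wraps),
                gravity=toy_limb.gravity,
            )
            act = solve_trial(model, pose, toy_torques, bound_override=500.0)
            assert act.converged
            usages.append(np.sum(np.abs(act.reserve)))
        assert usages[0] > 1e-3  # baseline muscles leave a real residual
        assert usages[1] <= 1e-6 or usages[1] < usages[0]
        assert usages[2] <= 1e-6  # ample capacity: reserves vanish

    def test_objective_monotone_in_bounds(self, toy_limb, toy_gait, toy_torques):
        """Enlarging reserve bounds never increases the muscle effort."""
        pose, _ = toy_gait
        totals = []
        for bound in (100.0, 300.0, 1000.0):
            act = solve_trial(toy_limb, pose, toy_torques, bound_override=bound)
            assert act.converged
            totals.append(np.sum(act.objective))
        assert totals[1] <= totals[0] + 1e-6
        assert totals[2] <= totals[1] + 1e-6


class TestScanActuatorBounds:
    def test_muscle_sufficient_reports_start_value(self, toy_limb, toy_gait, toy_gravity_torques):
        """Without ground contact the toy muscles carry everything."""
        pose, _ = toy_gait
        scan = scan_actuator_bounds(toy_limb, pose, toy_gravity_torques)
        assert scan.bound == pytest.approx(1e-9)
        assert scan.conditions_met

    def test_zero_torque_trivial(self):
        model = _hinge_muscle_model()
        pose = _static_pose(model)
        scan = scan_actuator_bounds(
            model, pose, _constant_torque_series(model, pose, 0.0), include_passive=False
        )
        assert scan.bound == pytest.approx(1e-9)
        assert scan.conditions_met

    def test_half_capacity_bound_near_analytic_residual(self):
        """Muscle capacity r*fmax = 2 Nm against tau = 4 Nm: the scan must
        land within one refinement step of the tau/2 residual."""
        model = _hinge_muscle_model(fmax=100.0)
        pose = _static_pose(model)
        torques = _constant_torque_series(model, pose, 4.0)
        scan = scan_actuator_bounds(model, pose, torques, include_passive=False)
        assert scan.conditions_met
        assert 2.0 - 1e-9 <= scan.bound <= 2.0 * 10.0  # one decade refinement
        fine = scan_actuator_bounds(
            model, pose, torques, refine_decades=0.05, include_passive=False
        )
        assert 2.0 - 1e-9 <= fine.bound <= 2.0 * 10**0.05

    def test_reported_bound_in_tested_trace(self, toy_limb, toy_gait, toy_torques):
        pose, _ = toy_gait
        scan = scan_actuator_bounds(toy_limb, pose, toy_torques)
        assert scan.conditions_met
        tested_bounds = [b for b, ok in scan.tested]
        assert scan.bound in tested_bounds
        assert dict(scan.tested)[scan.bound] is True

    def test_unreachable_demand_fails_at_cap(self):
        model = _hinge_muscle_model(fmax=1.0)
        pose = _static_pose(model)
        torques = _constant_torque_series(model, pose, 1e6)
        scan = scan_actuator_bounds(model, pose, torques, include_passive=False)
        assert not scan.conditions_met
        assert scan.bound == np.inf


def _sweep_model(tau_y):
    """Single link, sagittal hinge base; muscles span rz and ry."""
    segments = {"base": Segment("base"), "a": Segment("a", 0.0, inertia=np.zeros(3))}
    joints = [
        Joint("root", "ground", "base"),
        Joint("j", "base", "a", dof_flags=(False, False, True, False, False, False)),
    ]
    muscles = []
    # four oblique muscles whose arms cover both signs about rz and ry
    attachments = [
        ((0.08, 0.08, 0.02), (0.02, -0.1, -0.02)),
        ((-0.08, 0.08, -0.02), (-0.02, -0.1, 0.02)),
        ((0.08, 0.08, -0.02), (0.02, -0.1, 0.02)),
        ((-0.08, 0.08, 0.02), (-0.02, -0.1, -0.02)),
    ]
    for i, (org, ins) in enumerate(attachments):
        muscles.append(
            Muscle(
                path=MusclePath(f"m{i}", (("base", org), ("a", ins))),
                params=MuscleParams(ml=0.2, fl=0.2, fmax=300.0, pcsa=1e-3, tendon_slack=0.0),
            )
        )
    model = ModelConfig(segments=segments, joints=joints, muscles=muscles)
    pose = _static_pose(model)
    n = pose.n_samples
    torques = TorqueSeries(
        time=pose.time,
        moment={"j": np.tile([0.0, tau_y, 0.5], (n, 1)), "root": np.zeros((n, 3))},
        force={"j": np.zeros((n, 3)), "root": np.zeros((n, 3))},
    )
    return model, pose, torques


class TestDofSweep:
    def test_base_sufficient_stops_immediately(self):
        model, pose, torques = _sweep_model(tau_y=0.0)
        chosen, steps = dof_sweep(model, [("j", 1)], pose, torques, include_passive=False)
        assert steps[0].accepted and not steps[1].accepted
        assert not chosen.joint_by_name("j").dof_flags[1]

    def test_out_of_plane_torque_adds_the_needed_dof(self):
        model, pose, torques = _sweep_model(tau_y=0.4)
        chosen, steps = dof_sweep(model, [("j", 1)], pose, torques, include_passive=False)
        assert steps[1].accepted
        assert chosen.joint_by_name("j").dof_flags[1]
        assert steps[1].score < steps[0].score

    def test_constant_evaluation_stops_after_first_addition(self):
        model, pose, torques = _sweep_model(tau_y=0.0)
        chosen, steps = dof_sweep(
            model, [("j", 1)], pose, torques,
            evaluation=lambda act, scan: 1.0, include_passive=False,
        )
        assert len(steps) == 2 and not steps[1].accepted
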