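"""Static optimization: joint torques -> muscle activations + reserves.

At every frame the net joint torques from inverse dynamics are distributed
over the muscles by minimizing the sum of squared activations, with
non-biological reserve actuators at each joint DOF absorbing whatever
demand the muscles cannot meet.  With a rigid tendon the muscle force is
linear in activation, so each frame is a convex quadratic program over

    Σ_i r[i][j] F_i(a_i) + reserve_j = τ_j      for every enabled DOF j
    0 ≤ a_i ≤ 1,   |reserve_j| ≤ bound_j

solved lexicographically: first the bound-normalized reserve norm
``Σ_j (reserve_j / bound_j)²`` is minimized (reserve output "as small as
possible" — reserves are residual absorbers, not actuators to recruit),
then, with the reserves pinned at that minimum, the muscle effort
``Σ_i a_i²``.  Muscles therefore carry every torque they can; reserves
only ever take the part the muscles cannot.  Feasibility at given bounds
is probed with a linear program; both quadratic stages are solved by
SLSQP, deterministically.

``scan_actuator_bounds`` finds the minimal reserve bounds: scanning starts
at 1e-9 (N or Nm), ascends by factors of 10 until a solution exists, then
descends by log-space bisection until both stop conditions hold — (a) the
solve converges and (b) every muscle stays below its maximum force.
``dof_sweep`` orchestrates the model-mobility search, enabling one DOF at a
time from the most distal joint to the most proximal and stopping when the
addition no longer improves the evaluation score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linprog, lsq_linear, minimize

from .inverse_dynamics import TorqueSeries, generalized_forces
from .kinematics import PoseSeries
from .model_core import Joint, ModelConfig
from .muscle_mechanics import (
    MomentArmMatrix,
    active_force_length,
    fibre_state,
    moment_arms,
    passive_force_length,
    path_length,
)

__all__ = [
    "FrameSolution",
    "ActivationSeries",
    "ActuatorScanResult",
    "solve_frame",
    "solve_trial",
    "scan_actuator_bounds",
    "dof_sweep",
]

RESERVE_WEIGHT = 1.0
KKT_TOL = 1e-8
MAX_ITER = 500
SCAN_START = 1e-9
SCAN_CAP = 1e3


@dataclass
class FrameSolution:
    activations: np.ndarray  # (n_muscles,)
    reserves: np.ndarray  # (n_dofs,)
    objective: float  # sum of squared activations
    residual: float  # max torque-balance violation
    status: str  # "ok" | "infeasible" | "failed"


@dataclass
class ActivationSeries:
    """Muscle activations and reserve-actuator usage over the stride."""

    time: np.ndarray
    muscles: list[str]
    coordinates: list[tuple[str, int]]
    a: np.ndarray  # (n_muscles, n_frames), in [0, 1]
    reserve: np.ndarray  # (n_dofs, n_frames)
    objective: np.ndarray  # (n_frames,) sum of squared activations
    failed_frames: list[int] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return not self.failed_frames


def solve_frame(
    tau: np.ndarray,
    R: np.ndarray,
    gains: np.ndarray,
    bounds: np.ndarray,
    passive: np.ndarray | None = None,
    x0: np.ndarray | None = None,
) -> FrameSolution:
    """Resolve one frame's torques into activations and reserves.

    Parameters
    ----------
    tau:
        Net generalized forces, shape (n_dofs,).
    R:
        Moment-arm matrix, shape (n_muscles, n_dofs).
    gains:
        Active force per unit activation along the tendon for each muscle
        at this pose: ``fmax * f_L(l̃) * cos(alpha)``.
    bounds:
        Reserve-actuator bounds per DOF (>= 0).
    passive:
        Activation-independent (passive) muscle forces, same shape as
        ``gains``; their torque contribution is moved to the right-hand
        side.
    x0:
        Warm-start activations/reserves (affects iterations only; the QP is
        strictly convex, so the solution is unique).
    """
    tau = np.asarray(tau, dtype=float).reshape(-1)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    gains = np.asarray(gains, dtype=float).reshape(-1)
    bounds = np.asarray(bounds, dtype=float).reshape(-1)
    nm, nd = R.shape
    if tau.size != nd or gains.size != nm or bounds.size != nd:
        raise ValueError("inconsistent shapes in solve_frame")
    if np.any(bounds < 0):
        raise ValueError("reserve bounds must be >= 0")
    rhs = tau.copy()
    if passive is not None:
        rhs = rhs - R.T @ (np.asarray(passive, dtype=float).reshape(-1))
    # A x = rhs with x = [a, reserve]; torque of muscle i on dof j = r[i,j] * gain_i * a_i
    A = np.hstack([(R * gains[:, None]).T, np.eye(nd)])
    lo = np.concatenate([np.zeros(nm), -bounds])
    hi = np.concatenate([np.ones(nm), bounds])

    # feasibility probe (deterministic LP)
    res = linprog(
        c=np.zeros(nm + nd),
        A_eq=A,
        b_eq=rhs,
        bounds=list(zip(lo, hi)),
        method="highs",
    )
    if not res.success:
        return FrameSolution(
            activations=np.zeros(nm),
            reserves=np.zeros(nd),
            objective=np.inf,
            residual=np.inf,
            status="infeasible",
        )

    x_init = res.x if x0 is None else np.clip(x0, lo, hi)

    # stage 1: reserves as small as possible.  With reserve = rhs - B a
    # (B the muscle torque map) this is a bounded-variable least-squares
    # problem min ||diag(1/bound) (B a - rhs)|| over 0 <= a <= 1.
    B = A[:, :nm]
    D = 1.0 / np.maximum(bounds, 1e-30)
    ls = lsq_linear(B * D[:, None], rhs * D, bounds=(0.0, 1.0), method="bvls")
    a1 = ls.x
    reserve_star = rhs - B @ a1
    if np.any(np.abs(reserve_star) > bounds * (1 + 1e-9) + 1e-12):
        # a reserve bound binds at the least-squares point; re-minimize the
        # reserve norm with the bound constraints active (rare)
        w_res = np.concatenate([np.zeros(nm), D**2])
        sol1 = minimize(
            lambda x: float(x @ (w_res * x)),
            x_init,
            jac=lambda x: 2.0 * w_res * x,
            bounds=list(zip(lo, hi)),
            constraints=[{"type": "eq", "fun": lambda x: A @ x - rhs, "jac": lambda x: A}],
            method="SLSQP",
            options={"maxiter": MAX_ITER, "ftol": KKT_TOL},
        )
        if not sol1.success:
            return FrameSolution(
                activations=np.clip(x_init[:nm], 0, 1), reserves=x_init[nm:],
                objective=np.inf, residual=np.inf, status="failed",
            )
        a1, reserve_star = sol1.x[:nm], sol1.x[nm:]

    # stage 2: minimal muscle effort at the reserve-minimal residual
    tau_muscle = rhs - reserve_star
    sol2 = minimize(
        lambda a: float(a @ a),
        a1 if x0 is None else np.clip(x0[:nm], 0.0, 1.0),
        jac=lambda a: 2.0 * a,
        bounds=[(0.0, 1.0)] * nm,
        constraints=[{"type": "eq", "fun": lambda a: B @ a - tau_muscle,
                      "jac": lambda a: B}],
        method="SLSQP",
        options={"maxiter": MAX_ITER, "ftol": KKT_TOL},
    )
    a = np.clip(sol2.x if sol2.success else a1, 0.0, 1.0)
    x = np.concatenate([a, reserve_star])
    residual = float(np.max(np.abs(A @ x - rhs))) if nd else 0.0
    status = "ok" if residual < 1e-6 else "failed"
    return FrameSolution(
        activations=a,
        reserves=reserve_star,
        objective=float(a @ a),
        residual=residual,
        status=status,
    )


def _frame_setup(
    model: ModelConfig,
    q: dict[str, np.ndarray],
    coordinates: list[tuple[str, int]],
    include_passive: bool,
    h: float = 1e-6,
):
    """Moment arms, activation gains, and passive forces at one pose."""
    R = moment_arms(model, q, h=h, coordinates=coordinates)
    gains = np.zeros(len(model.muscles))
    passive = np.zeros(len(model.muscles))
    for i, mus in enumerate(model.muscles):
        l_mt = path_length(model, mus, q).length
        p = mus.params
        try:
            l_norm, cos_a = fibre_state(l_mt, p)
        except Exception:
            l_norm, cos_a = 1.0, float(np.cos(p.alpha))
        gains[i] = p.fmax * active_force_length(l_norm) * cos_a
        if include_passive:
            passive[i] = p.fmax * passive_force_length(l_norm) * cos_a
    return R, gains, passive


def _bounds_vector(model: ModelConfig, coordinates, override: float | None) -> np.ndarray:
    if override is not None:
        return np.full(len(coordinates), float(override))
    out = np.zeros(len(coordinates))
    for k, (jname, dof) in enumerate(coordinates):
        out[k] = model.joint_by_name(jname).actuator_bounds[dof]
    return out


def solve_trial(
    model: ModelConfig,
    pose: PoseSeries,
    torques: TorqueSeries,
    bound_override: float | None = None,
    include_passive: bool = True,
    include_ground: bool = False,
    warm_start: bool = True,
) -> ActivationSeries:
    """Frame-by-frame static optimization over a trial.

    Torques (lab frame) are projected onto the enabled DOF axes; each frame
    is solved independently, warm-started from the previous frame (speed
    only — the per-frame QP has a unique optimum).  Infeasible frames are
    recorded in ``failed_frames`` and hold zeros.
    """
    coords = model.coordinates(include_ground=include_ground)
    gen = generalized_forces(torques, model, pose)
    bounds = _bounds_vector(model, coords, bound_override)
    n = pose.n_samples
    nm = len(model.muscles)
    a = np.zeros((nm, n))
    reserve = np.zeros((len(coords), n))
    objective = np.zeros(n)
    failed: list[int] = []
    x_prev = None
    for i in range(n):
        q, _, _ = pose.frame(i)
        R, gains, passive = _frame_setup(model, q, coords, include_passive)
        tau = np.array([gen[c][i] for c in coords])
        sol = solve_frame(
            tau, R.r, gains, bounds, passive=passive, x0=x_prev if warm_start else None
        )
        if sol.status != "ok":
            failed.append(i)
            continue
        a[:, i] = sol.activations
        reserve[:, i] = sol.reserves
        objective[i] = sol.objective
        x_prev = np.concatenate([sol.activations, sol.reserves])
    return ActivationSeries(
        time=pose.time.copy(),
        muscles=[m.name for m in model.muscles],
        coordinates=coords,
        a=a,
        reserve=reserve,
        objective=objective,
        failed_frames=failed,
    )


@dataclass
class ActuatorScanResult:
    """Outcome of the reserve-actuator bound scan."""

    bound: float  # minimal passing scalar bound
    per_dof: dict[tuple[str, int], float]
    tested: list[tuple[float, bool]]  # (bound, converged) trace
    converged: bool  # condition (a)
    muscles_below_fmax: bool  # condition (b)

    @property
    def conditions_met(self) -> bool:
        return self.converged and self.muscles_below_fmax


def _muscle_force_cap_ok(model: ModelConfig, pose: PoseSeries, act: ActivationSeries) -> bool:
    """Condition (b): every muscle force stays below fmax scaled by its
    force-length headroom at the frame's pose."""
    for i in range(pose.n_samples):
        q, _, _ = pose.frame(i)
        for k, mus in enumerate(model.muscles):
            l_mt = path_length(model, mus, q).length
            p = mus.params
            try:
                l_norm, cos_a = fibre_state(l_mt, p)
            except Exception:
                l_norm, cos_a = 1.0, float(np.cos(p.alpha))
            f = (
                act.a[k, i] * active_force_length(l_norm) + passive_force_length(l_norm)
            ) * p.fmax * cos_a
            cap = p.fmax * (active_force_length(l_norm) + passive_force_length(l_norm)) * cos_a
            if f > cap * (1 + 1e-9):
                return False
    return True


def scan_actuator_bounds(
    model: ModelConfig,
    pose: PoseSeries,
    torques: TorqueSeries,
    start: float = SCAN_START,
    factor: float = 10.0,
    refine_decades: float = 1.0,
    cap: float = SCAN_CAP,
    include_passive: bool = True,
) -> ActuatorScanResult:
    """Minimal reserve-actuator bound by exponential ascent + log bisection.

    A single scalar bound is applied to every enabled DOF.  Starting at
    1e-9 (N or Nm), the bound is multiplied by ``factor`` until the trial
    solves; the interval between the last failing and first passing bound
    is then bisected in log space until it is narrower than
    ``refine_decades`` decades, keeping the smallest bound at which both
    conditions hold: (a) all frames converge and (b) all muscle forces stay
    below their maxima.
    """

    def attempt(b: float) -> tuple[bool, ActivationSeries]:
        act = solve_trial(model, pose, torques, bound_override=b, include_passive=include_passive)
        ok = act.converged and _muscle_force_cap_ok(model, pose, act)
        return ok, act

    tested: list[tuple[float, bool]] = []
    b = start
    ok, act = attempt(b)
    tested.append((b, ok))
    while not ok:
        if b > cap:
            return ActuatorScanResult(
                bound=np.inf,
                per_dof={},
                tested=tested,
                converged=False,
                muscles_below_fmax=False,
            )
        b *= factor
        ok, act = attempt(b)
        tested.append((b, ok))
    # descending refinement between last failing and first passing bound
    if len(tested) > 1:
        lo = tested[-2][0]  # failed
        hi = b  # passed
        while np.log10(hi / lo) > refine_decades + 1e-12:
            mid = 10 ** ((np.log10(lo) + np.log10(hi)) / 2.0)
            ok_mid, act_mid = attempt(mid)
            tested.append((mid, ok_mid))
            if ok_mid:
                hi, act = mid, act_mid
            else:
                lo = mid
        b = hi
    coords = model.coordinates(include_ground=False)
    return ActuatorScanResult(
        bound=float(b),
        per_dof={c: float(b) for c in coords},
        tested=tested,
        converged=True,
        muscles_below_fmax=True,
    )


def _enable_dof(model: ModelConfig, joint_name: str, dof: int) -> ModelConfig:
    joints = []
    for j in model.joints:
        if j.name == joint_name:
            flags = list(j.dof_flags)
            flags[dof] = True
            j = replace(j, dof_flags=tuple(flags))
        joints.append(j)
    return ModelConfig(
        segments=dict(model.segments),
        joints=joints,
        muscles=list(model.muscles),
        wraps=dict(model.wraps),
        gravity=model.gravity.copy(),
        ground=model.ground,
    )


@dataclass
class SweepStep:
    added: tuple[str, int] | None  # (joint, dof) enabled at this step
    dofs: int
    score: float
    bound: float
    accepted: bool


def default_evaluation(act: ActivationSeries, scan: ActuatorScanResult) -> float:
    """Summed reserve-actuator usage (the default model-selection score)."""
    return float(np.sum(np.abs(act.reserve)))


def dof_sweep(
    base_model: ModelConfig,
    candidates: Sequence[tuple[str, int]],
    pose: PoseSeries,
    torques: TorqueSeries,
    evaluation: Callable[[ActivationSeries, ActuatorScanResult], float] | None = None,
    rel_improvement: float = 1e-9,
    abs_improvement: float = 1e-6,
    **scan_kwargs,
) -> tuple[ModelConfig, list[SweepStep]]:
    """Greedy mobility search over joint DOFs, distal to proximal.

    Starting from the base (typically all-sagittal, hinge-only) model, one
    candidate DOF at a time is enabled in the given order — the most distal
    joint first — and the actuator scan plus trial solve are re-run.  A
    configuration's score is the evaluation of its solution plus the torque
    demand at still-disabled candidate DOFs (demand a locked joint absorbs
    as constraint load rather than muscle force); enabling a DOF the
    muscles can balance therefore improves the score.  The addition is
    kept while the score improves; the sweep stops at the first
    non-improving addition.  Returns the selected model and the step trace.
    """
    evaluation = evaluation or default_evaluation
    from .model_core import count_dofs  # local to avoid cycle at import time

    candidate_load = generalized_forces(torques, base_model, pose, coordinates=list(candidates))
    include_passive = scan_kwargs.get("include_passive", True)

    def run(model: ModelConfig) -> tuple[float, ActuatorScanResult]:
        scan = scan_actuator_bounds(model, pose, torques, **scan_kwargs)
        if not scan.conditions_met:
            return np.inf, scan
        act = solve_trial(
            model, pose, torques, bound_override=scan.bound, include_passive=include_passive
        )
        locked = sum(
            float(np.sum(np.abs(candidate_load[(jn, d)])))
            for jn, d in candidates
            if not model.joint_by_name(jn).dof_flags[d]
        )
        try:
            return float(evaluation(act, scan)) + locked, scan
        except Exception as e:  # pluggable evaluation must be computable
            raise RuntimeError(f"evaluation function failed: {e}") from e

    model = base_model
    score, scan = run(model)
    steps = [SweepStep(None, count_dofs(model), score, scan.bound, True)]
    for joint_name, dof in candidates:
        trial_model = _enable_dof(model, joint_name, dof)
        trial_score, trial_scan = run(trial_model)
        improved = trial_score < score - max(rel_improvement * abs(score), abs_improvement) or (
            score == np.inf and trial_score < np.inf
        )
        steps.append(
            SweepStep((joint_name, dof), count_dofs(trial_model), trial_score,
                      trial_scan.bound, improved)
        )
        if improved:
            model, score = trial_model, trial_score
        else:
            break
    return model, steps
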