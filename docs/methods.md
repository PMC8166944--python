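# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `caninemsk`, in the order of the analysis chain.

## Model representation

A model is a rooted tree of rigid segments joined by joints. Each joint
carries six per-axis DOF switches — rotations rx, ry, rz (intrinsic XYZ
Cardan sequence, body-fixed axes) and translations tx, ty, tz — plus
per-DOF reserve-actuator bounds. The child frame is placed at

    o_c = o_p + R_p (t_frame + R_frame t_q),
    R_c = R_p R_frame Rx(rx) Ry(ry) Rz(rz),

with translations applied in the joint frame before the rotations.
Validation enforces a single tree rooted at the ground segment, symmetric
positive-semidefinite inertia tensors whose principal moments satisfy the
rigid-body triangle inequalities, and referential integrity of muscle
points and wrap obstacles. Local x is protraction/retraction
(flexion/extension), y abduction/adduction, z axial rotation/mediolateral;
gravity defaults to (0, −9.81, 0) m/s²; SI units throughout.

Sagittal mirroring reflects geometry with S = diag(1, 1, −1): positions map
to S·p, rotations to S·R·S (again proper), inertia to S·I·S; muscle
parameters are copied unchanged. Mirroring is an involution to machine
precision.

### Packaged dog configuration

The whole-dog configuration realizes the published topology and counts: a
free-floating base (3 translational DOFs, excluded from the model's DOF
count — whether the printed total includes the ground joint is not stated,
so the package adopts the exclusive reading), four axial bodies with 3
rotational DOFs each, 15 DOFs per forelimb (scapula 5 = 3 rotations +
anterior-posterior and vertical translation, shoulder 3, elbow 2, carpal 2,
forepaw 3) and 21 per hindlimb (pelvis 5, hip 3, stifle 2, tarsal 2,
hindpaw 3, toes 6 lumped), totalling 84. The hindlimb split is a
configuration choice constrained only by the total — it is not reported
anatomy. Forelimb reserve-actuator bounds follow the published parameter
map; because the source table's cell boundaries are typographically
ambiguous, the affected joints carry `bounds_verified=False`. The muscle
registry lists 67 muscles per side by standard canine anatomical names;
attachment coordinates, muscle parameters, and inertial values are
synthetic placeholders chosen to be dimensionally plausible — the packaged
model's verifiable content is its topology, DOF allocation, and counts,
not individual-specific geometry.

## Kinematics

Cardan-to-quaternion conversion and the XYZ decomposition are delegated to
`scipy.spatial.transform.Rotation`; quaternions are scalar-first,
normalized, and canonicalized to w ≥ 0, with nearest-neighbour sign
continuity available for time series. Relative joint rotation between an
upper and lower segment is q_lower* ⊗ q_upper (equivalently R_lowerᵀ
R_upper), decomposed back to intrinsic XYZ angles; poses with |ry| within
1e−6 of π/2 are flagged as gimbal-proximal rather than rejected. The
intrinsic (body-fixed) reading of the XYZ sequence is a documented
convention choice.

Filtering is a 4th-order Butterworth applied forward-backward (zero phase)
at a 6 Hz default cutoff for kinematic and ground-reaction channels — the
conventional gait-analysis configuration. Differentiation uses central
differences with second-order one-sided boundary stencils (exact through
quadratics). Gait normalization resamples touchdown-to-touchdown onto a
101-point 0–100% grid and records the stance fraction.

## Inverse dynamics

The recursion propagates lab-frame orientation, angular velocity and
acceleration, and frame-origin acceleration outward from the root. For the
intrinsic XYZ joint rotation the relative body-frame angular velocity is

    ω_rel = ṙx·(Rzᵀ Ryᵀ e_x) + ṙy·(Rzᵀ e_y) + ṙz·e_z,

and its derivative follows by differentiating the axis vectors;
translational DOFs contribute the full transport, centripetal, and
Coriolis terms. Gravity enters through the standard device of accelerating
the root frame by −g. The inward pass sums segment inertial wrenches
(F = m·a_com, N = I·α + ω×Iω about the COM), external loads (GRF applied
at the centre of pressure of the paw segment; an optional free moment
defaults to zero), and child joint wrenches in depth-first post-order,
reporting the intersegmental force and the moment about each joint's
child-frame origin. The residual wrench at ground-rooted joints is
reported, not zeroed — it is the demand the global reserve actuators
absorb. Everything is double precision; because recursive formulations
accumulate error, the test suite cross-checks against an independent
Lagrangian oracle (below) on one hundred random chains and against the
classic hand-derived planar double-pendulum equations.

`generalized_forces` projects joint wrenches onto the instantaneous DOF
axes (R_pf e_x, R_pf Rx e_y, R_pf Rx Ry e_z for rotations; the joint-frame
basis for translations), making the output directly comparable to a
Lagrangian formulation. `apply_sign_convention` applies per-joint axis
flips so that retractor, adductor, and internal-rotation torques are
positive; a retractor torque flexes the shoulder, extends the elbow, and
flexes the carpal joint, which is why the flexion/extension flip
alternates along the forelimb. Joints without a registered convention keep
raw signs (recorded as a unit map), and the map is its own inverse.

### The Lagrangian oracle

The oracle computes generalized torques as
τ = d/dt(∂T/∂q̇) − ∂T/∂q + ∂V/∂q from its own forward-kinematics chain,
sharing nothing with the recursion but elementary trigonometry. Velocities
inside T are exact directional derivatives obtained by a complex step
(h = 1e−150) through the position map; the generalized momentum ∂T/∂q̇ is
exact because T is a quadratic form in q̇ (evaluated by symmetric finite
differences that are exact for quadratics); its time derivative uses
central differences of the *prescribed* trajectory at dt = 1e−5; and the
configuration gradients use central differences at dq = 1e−6. The combined
error is ~1e−9 relative — three orders below the 1e−6 agreement the tests
demand. This numeric construction was chosen over committed symbolic
equations because it needs no symbolic engine at runtime, covers every
chain topology without per-topology derivations, and stays genuinely
independent of the implementation under test; the double-pendulum
closed form in the tests adds a fully symbolic second witness.

## Muscle mechanics

Paths are polylines of attachment points. A straight segment that
penetrates a wrap obstacle is replaced by a tangent–arc–tangent
construction: spheres wrap along the great arc in the plane of the two
endpoints and the centre; cylinders wrap in the cross-section plane with
the axial coordinate distributed linearly along the developed (unwrapped)
path. The wrap side of a cylinder is chosen to minimize path length. Path
length is continuous across engagement/disengagement (verified to 1e−9
across the switching pose); a via point inside an obstacle is a geometry
error.

Moment arms use the tendon-excursion relation r = −∂L/∂q by central
differences, default step h = 1e−6 rad; coordinates a muscle does not span
(determined from the joint tree) are exact zeros. If the wrap state flips
within ±h the step is halved adaptively (warning after 5 halvings). A
muscle wrapped on a cylinder coaxial with a hinge has arm exactly equal to
the cylinder radius, which the tests use as a closed-form anchor.

The static muscle model is rigid-tendon Hill-type:
F = (a·f_L(ℓ̃) + f_P(ℓ̃))·Fmax·cos α, with the fibre spanning the
musculotendon length minus the tendon slack length under constant-thickness
pennation (w = fl·sin α fixed). The active curve is a Gaussian
f_L = exp(−((ℓ̃−1)/0.45)²) (peak 1 at optimal length, width 0.45); the
passive curve is zero at or below optimal length and rises exponentially,
normalized to 1 at ℓ̃ = 1.7. These documented closed forms stand in for
spline-based curve families whose exact coefficients are not part of the
contract — the properties that matter (unimodal active peak at 1, passive
zero below 1 and monotone above) are tested. Force-velocity scaling is
deliberately absent: static optimization treats each frame independently.
Tendon length, when not measured, is estimated as tl = ml − fl·cos α,
clipped at zero with a warning. Whether passive force participates in the
torque balance is a toggle (`include_passive`), default on.

## Static optimization

With a rigid tendon, muscle force is affine in activation, so each frame
is a convex QP. It is solved *lexicographically*: stage 1 minimizes the
bound-normalized reserve norm Σ(ρⱼ/bⱼ)² — reserves are non-biological
residual absorbers whose output should be as small as possible, so they
are never recruited in place of available muscle; stage 2 minimizes the
muscle effort Σaᵢ² with the reserves pinned at that minimum. A
single-objective blend was considered and rejected: any finite weight
makes large-bound reserves cheaper than muscles, inverting the intended
roles (e.g. a single muscle with ample reserve bound would idle at
a ≈ 0.02 instead of the correct a = 0.5). Stage 1 is a bounded-variable
least-squares problem solved by `scipy.optimize.lsq_linear` (BVLS), with
an SLSQP fallback when a reserve bound binds; stage 2 is SLSQP with
analytic gradients (ftol 1e−8, ≤500 iterations). Feasibility is probed
first with a HiGHS linear program; an infeasible frame returns a status,
not an exception. Everything is deterministic — no random restarts — and
warm starts affect iteration counts only, since each stage has a unique
optimum. Torque-balance residuals above 1e−6 mark a frame failed.

The actuator scan applies one scalar bound to every enabled DOF: start
1e−9 (N or Nm), multiply by 10 until the whole trial solves, then bisect
downward in log space between the last failing and first passing bound
until the interval is narrower than the refinement tolerance (one decade
by default), keeping the smallest bound at which both stop conditions
hold: (a) every frame converges and (b) every muscle force stays below its
force-length-scaled maximum. Per-DOF granularity of the original parameter
map is preserved in the result type; the scalar schedule is the simplest
policy satisfying every stated property of the procedure.

The DOF sweep enables one candidate DOF at a time, most distal joint
first, re-running scan + solve. A configuration's score is the (pluggable)
evaluation of its solution — default: summed reserve usage — plus the
torque demand at still-disabled candidate DOFs, which a locked joint
absorbs as constraint load; enabling a DOF whose demand the muscles can
balance therefore improves the score. The sweep keeps improving additions
(strict improvement beyond 1e−6 absolute) and stops at the first
non-improving one.

## Synergy clustering

Activations are floored at 2⁻¹⁰ ≈ 1e−3 before log2 — zero activation is
common (clipping, silent muscles) and would otherwise map to −∞; the floor
value is a documented choice placing silence ten octaves below full
activation. Euclidean distances between muscles are taken across the time
axis. Agglomeration uses the Ward.D2 convention (Lance–Williams update on
squared distances, square-root heights — two singletons merge at their
plain distance), computed by `scipy.cluster.hierarchy.linkage`; the test
suite re-derives merges with a brute-force Lance–Williams recomputation.
Minimal leaf sorting places the subtree with the smaller merge height
first at every internal node, ties broken by lowest original leaf index.

Grouping uses the longest branch lengths from the root: branch length is
the parent-child height difference, so the length from the root down to
any node telescopes to h_root − h_node. For each muscle, the longest edge
on its root-to-leaf path is located (ties resolve to the edge nearest the
root), and the subtree hanging below that edge is the muscle's main group;
subgroups re-apply the criterion inside each main group. Equal-length
sibling branches naturally produce sibling groups — three equidistant
clusters hang at the same length from the root — and a zero-height tree
yields a single group. The group count is data-driven, never forced to
three. Branch length (not node height) as the "length" is the operative
reading; it is what a dendrogram displays.

## Scaling

`fit_loglog` is ordinary least squares on log-transformed body mass and
per-limb totals (muscle mass, total PCSA), with the slope standard error
for uncertainty statements. Parameter transfer multiplies PCSA (and fmax
with it) by the fitted ratio ŷ(M_target)/ŷ(M_source), scales muscle mass
linearly with the body-mass ratio, and leaves length parameters untouched
— they ride on the geometric scaling of the skeleton. Where fmax is absent
from a morphometry table it is derived from PCSA via a specific tension of
3.0e5 N/m² (a documented default; the source studies do not state one).
Geometric scaling multiplies joint offsets, attachment points, COM
positions, and wrap radii by a limb or axial factor; masses and inertia
are deliberately left to the caller because geometric similarity does not
determine them. The packaged presets carry the published factor pair —
1.66 for limbs, 1.25 for spine/neck/head — under `beagle_to_gs` (the
direction in which the factors were derived: scaling the smaller skeleton
up to the donor muscle model) with `gs_to_beagle` as its inverse.

## Synthetic data

The generators are pure functions of (spec, seed).

**Pendulum chains** (`make_pendulum`) prescribe per-DOF sinusoids with
analytic derivatives — the oracle substrate for inverse-dynamics
validation. Default link inertia is a slender rod.

**Toy limb** (`make_toy_limb`): trunk fixed to ground, a scapula-analog on
a joint with anterior-posterior/vertical translations plus a hinge (the
mobility a muscle-slung shoulder girdle needs), hinge shoulder and elbow.
Eight muscles cover every DOF in both signs: protractor/retractor slings,
a vertical suspensor, a cranial+caudal depressor pair (their fore-aft
components cancel so the pair can bear the stance load), a shoulder
flexor, a biarticular extensor spanning shoulder and elbow, and an elbow
flexor wrapped over a cylinder coaxial with the hinge. Fibre lengths are
frozen at default-pose path lengths so the force-length curve operates
near its optimum.

**Synthetic gait** (`make_synthetic_gait`): every enabled DOF oscillates
at the stride frequency (rotations ~0.08–0.2 rad amplitude, translations
4–10 mm, seeded), making the stride exactly periodic with analytic
derivatives. The vertical GRF is a single-stance half-sine-squared pulse
whose impulse is a configured fraction (default 0.3) of body weight ×
stride time — one limb of a walking quadruped carries roughly a third of
the impulse; the fore-aft component brakes in early stance and propels in
late stance at 20% of the vertical amplitude; the load vanishes in swing;
the centre of pressure tracks under the paw. Defaults: 0.5 s stride, 60%
duty factor, 101 samples.

**Planted synergies** (`make_planted_activations`): the stride is split
into six phase windows (early/mid/late stance, early/mid/late swing);
each of three motif families is active (0.85) in two consecutive windows
over a 0.2 baseline — stance-extensor-like, transition-like,
swing-protractor-like — so every family pair differs over the same number
of samples and the three families sit at equal pairwise log-space
distances (three groups hanging at the same length from the root);
subgroup 1 fills only the first window of its family, making subgroup
splits strictly tighter than family splits. Gaussian noise (default
σ = 0.05) is added *before* clipping to [0, 1]: clipping at zero creates
exactly the zero-activation mass that the log floor must absorb. A
separate archetype generator provides whole-stance extensors, swing
protractors, and a cranial-to-caudal travelling wave across serratus-like
slips for qualitative checks.

What the synthetic data do *not* emulate: soft-tissue artifact, marker
noise and gap structure, force-plate drift, inter-stride variability,
co-contraction, and realistic anatomical geometry. Passing tests therefore
demonstrate algorithmic correctness under clean, controlled conditions —
not predictive validity for any real animal.

## Problem sizes and tolerances

The test suite and the acceptance script run small problems by choice: 100
random 1–3-link chains at 7 time samples for the oracle comparison (worst
relative disagreement ~3e−9 against a 1e−6 requirement), 21-frame trials
on the 8-muscle toy limb, 24×101 planted-synergy matrices over 100 seeds.
Key tolerances: quaternion round-trip 1e−10, wrap-length continuity 1e−9,
moment arms 1e−8 against analytic derivatives with verified O(h²)
convergence, QP torque residual 1e−6, Ward heights 1e−10 against the
brute-force oracle.

## Known limitations

* Static optimization ignores activation dynamics and force-velocity
  effects; it cannot capture co-contraction (minimizing Σa² actively
  discourages it), and joint stabilization therefore falls to the reserve
  actuators, as it did in the study design this mirrors.
* One wrap obstacle per path segment; no multi-obstacle chaining.
* The packaged dog model's geometry and parameters are placeholders; only
  its topology, DOF allocation, bounds placement, and counts are
  meaningful.
* The DOF sweep is greedy and order-dependent (distal to proximal by
  design); it reports its trace rather than claiming global optimality.
* Storage/TRC readers cover the tab-delimited dialects used here, not
  every variant in the wild; C3D is out of scope.
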