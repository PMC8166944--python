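# caninemsk

A musculoskeletal analysis toolkit for quadruped (dog) locomotion. It takes
segment kinematics and measured ground-reaction forces through the full
inverse-simulation chain:

1. **Joint kinematics** — segmental orientations (intrinsic XYZ Cardan
   angles) are converted to quaternions, composed into relative joint
   angles, low-pass filtered (zero-phase Butterworth, 6 Hz default),
   differentiated, and normalized to the gait cycle.
2. **Inverse dynamics** — a 3-D recursive Newton–Euler pass over the
   branched segment tree yields the net intersegmental force and moment at
   every joint, expressed in joint-local frames (x flexion/extension,
   y abduction/adduction, z axial rotation).
3. **Static optimization** — at every frame the net torques τ are resolved
   into muscle activations *a* and reserve-actuator torques ρ under

   ```
   Σᵢ rᵢⱼ Fᵢ(aᵢ) + ρⱼ = τⱼ,   0 ≤ aᵢ ≤ 1,   |ρⱼ| ≤ bⱼ,
   ```

   with rigid-tendon Hill-type muscle forces
   `Fᵢ(aᵢ) = (aᵢ f_L(ℓ̃ᵢ) + f_P(ℓ̃ᵢ))·Fmaxᵢ·cos αᵢ` and tendon-excursion
   moment arms `rᵢⱼ = −∂Lᵢ/∂qⱼ`. Reserve output is kept as small as
   possible (it is minimized first, then the muscle effort Σaᵢ²), and a
   parameter scan finds the minimal reserve bounds bⱼ: start at 1e−9,
   ascend ×10 until the trial solves, then bisect down in log space while
   (a) the solve converges and (b) every muscle stays below its maximum
   force.
4. **Muscle synergies** — activation time series are floored and
   log2-transformed, pairwise Euclidean distances feed Ward.D2
   agglomerative clustering, leaves are arranged by minimal leaf sorting,
   and muscles are sorted into main groups and subgroups by the longest
   branch lengths from the dendrogram root.

Around this pipeline sit the model-building computations: tendon-length
estimation `tl = ml − fl·cos α`, allometric scaling of PCSA and muscle mass
between body sizes (log-log least squares), geometric limb/axial scale
factors (packaged presets carry the published 1.66 / 1.25 pair), sagittal
mirroring of a limb, muscle-path wrapping over spheres (ball-and-socket
joints) and cylinders (hinge joints), and a greedy distal-to-proximal
degree-of-freedom (DOF) sweep that stops when added mobility no longer
improves the solution.

A packaged whole-dog configuration mirrors the published topology: 84 DOFs
at maximum mobility (12 axial + 2×15 forelimb + 2×21 hindlimb, free-floating
base excluded) and 134 muscles (67 per side, the right side an exact
mirrored copy of the left). The left-forelimb evaluation model carries the
printed allocation — scapula 5 (including anterior-posterior and vertical
translations for the muscle-slung shoulder girdle), shoulder 3, elbow 2,
carpal 2, forepaw 3 = 15 DOFs. Attachment coordinates and inertial values
in the packaged configuration are synthetic placeholders on that real
topology; see `docs/methods.md`.

The toolkit is for locomotion researchers and veterinary biomechanists who
want to estimate joint loads and muscle activation patterns non-invasively,
and to compress activation patterns into synergistic muscle groups for
neuromechanical modelling.

## Worked example

Resolve a synthetic walking trial on the built-in three-segment toy limb
(`examples/03_static_optimization_toy_limb.py`):

```python
from caninemsk import newton_euler
from caninemsk.static_optimization import scan_actuator_bounds, solve_trial
from caninemsk.synthetic import make_synthetic_gait, make_toy_limb

model = make_toy_limb()
pose, loads = make_synthetic_gait(model, seed=0, n_points=21)
torques = newton_euler(model, pose, loads)
scan = scan_actuator_bounds(model, pose, torques)
act = solve_trial(model, pose, torques, bound_override=scan.bound)
```

which prints

```
actuator scan: minimal reserve bound 10 (Nm / N), conditions met: True
  ladder: 1e-09- -> 1e-08- -> 1e-07- -> 1e-06- -> 1e-05- -> 0.0001- -> 0.001- -> 0.01- -> 0.1- -> 1- -> 10+

trial solved on 21 frames; peak activations:
  protractor_sling        0.94 #####################################
  retractor_sling         0.75 #############################
  serratus_analog         0.18 #######
  depressor_cranialis     1.00 ########################################
  depressor_caudalis      1.00 #######################################
  shoulder_flexor         0.43 #################
  biarticular_extensor    0.97 ######################################
  wrapped_elbow_flexor    0.71 ############################
max |reserve| used: 2.214
```

Reading the numbers: the scan ladder fails (−) at every bound up to 1 Nm
and first passes (+) at 10 Nm, so some frame needs a reserve of between 1
and 10 Nm — the solve confirms a peak residual of 2.2 Nm that the eight
muscles cannot span. The weight-bearing muscles (the depressor pair and
the biarticular extensor) peak near full activation during stance, while
swing-phase muscles stay low; activations are bounded in [0, 1] by
construction.

The other example scripts build the packaged dog model
(`01_build_dog_model.py`), validate the Newton–Euler recursion against an
independent Lagrangian oracle (`02_inverse_dynamics_pendulum.py`), recover
planted muscle synergies (`04_muscle_synergies.py`), and fit/apply the
scaling rules (`05_scaling.py`). A thin command-line shell exposes the same
pipelines (`caninemsk id|so|scan|sweep|synergy|scale|fixture`).

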