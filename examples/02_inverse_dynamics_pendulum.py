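"""Joint torques of a swinging double pendulum by recursive Newton-Euler.

Builds a two-link chain with prescribed sinusoidal motion, runs the
inverse-dynamics recursion, and cross-checks the generalized torques
against an independent Lagrangian oracle — the same validation the test
suite applies to one hundred random chains.
"""

import numpy as np

from caninemsk import newton_euler
from caninemsk.inverse_dynamics import generalized_forces
from caninemsk.synthetic import PendulumSpec, lagrangian_torque_oracle, make_pendulum

spec = PendulumSpec(
    masses=(1.2, 0.7), lengths=(0.3, 0.25), com_fracs=(0.45, 0.6),
    axes=(("z",), ("z",)),
    motion=({"z": (0.2, 0.5, 0.9, 0.3)}, {"z": (-0.4, 0.6, 1.3, 1.1)}),
)
t = np.linspace(0.0, 1.0, 11)
model, pose = make_pendulum(spec, time=t)

torques = newton_euler(model, pose)
gen = generalized_forces(torques, model, pose)
oracle = lagrangian_torque_oracle(spec, t)

print("time [s]   shoulder tau [Nm]   elbow tau [Nm]   (oracle in parens)")
for k in (0, 5, 10):
    print(f"{t[k]:6.2f}   {gen[('joint0', 2)][k]:12.4f} ({oracle[k, 0]:8.4f})"
          f"   {gen[('joint1', 2)][k]:10.4f} ({oracle[k, 1]:8.4f})")

err = max(
    np.max(np.abs(gen[("joint0", 2)] - oracle[:, 0])),
    np.max(np.abs(gen[("joint1", 2)] - oracle[:, 1])),
)
print(f"\nmax |Newton-Euler - Lagrangian| over the trial: {err:.2e} Nm")
print("The two formulations agree to solver precision: the recursion is "
      "algebraically exact, and the oracle's derivatives are numerically tight.")
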