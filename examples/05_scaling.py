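"""Allometric and geometric scaling between breeds.

Fits the log-log relationship between body mass and total limb PCSA on a
synthetic morphometry sample, transfers one muscle's parameters to a new
body mass, and applies the packaged limb/axial geometric scale factors.
"""

import numpy as np

from caninemsk import count_dofs
from caninemsk.model_core import MuscleParams
from caninemsk.muscle_mechanics import path_length
from caninemsk.scaling import SCALE_PRESETS, fit_loglog, scale_geometry, scale_muscle_params
from caninemsk.synthetic import make_toy_limb

# synthetic per-individual totals: PCSA ~ M^(2/3) with biological scatter
rng = np.random.default_rng(42)
body_mass = rng.uniform(6.0, 45.0, 11)  # kg, small to large dogs
total_pcsa = 8e-4 * body_mass ** (2 / 3) * np.exp(rng.normal(0, 0.08, 11))
fit = fit_loglog(body_mass, total_pcsa)
print(f"allometric fit over {fit.n} individuals: "
      f"log(PCSA) = {fit.slope:.3f} log(M) + {fit.intercept:.3f} "
      f"(slope SE {fit.slope_se:.3f})")

params = MuscleParams(m=0.06, ml=0.15, fl=0.07, alpha=0.2, pcsa=2.4e-4, fmax=72.0)
scaled = scale_muscle_params(params, fit, target_mass=9.0, source_mass=30.0)
print(f"\nmuscle transfer 30 kg -> 9 kg: pcsa {params.pcsa:.2e} -> {scaled.pcsa:.2e} m^2, "
      f"fmax {params.fmax:.0f} -> {scaled.fmax:.1f} N, mass {params.m:.3f} -> {scaled.m:.3f} kg")
print("(length parameters ride on the geometric scaling instead)")

limb_f, axial_f = SCALE_PRESETS["beagle_to_gs"]
toy = make_toy_limb()
big = scale_geometry(toy, limb_f, axial_f)
m = toy.muscles[0]
print(f"\ngeometric preset 'beagle_to_gs' (limb x{limb_f}, axial x{axial_f}):")
print(f"  {m.name} path length {path_length(toy, m).length:.4f} m -> "
      f"{path_length(big, m.name).length:.4f} m")
print(f"  DOF count unchanged: {count_dofs(toy, include_ground=True)}")
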