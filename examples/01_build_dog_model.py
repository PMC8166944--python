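"""Assemble the packaged whole-dog model and inspect its configuration.

Builds the bilateral maximum-mobility model and the left-forelimb
evaluation configuration, and prints their degree-of-freedom allocation
and muscle registry sizes.
"""

from caninemsk import count_dofs
from caninemsk.dog_model import (
    FORELIMB_DOF_BREAKDOWN,
    build_dog_model,
    build_forelimb_model,
)

dog = build_dog_model()
print(f"whole-dog model: {count_dofs(dog)} DOFs at maximum mobility "
      f"({count_dofs(dog, include_ground=True)} with the free-floating base)")
print(f"muscle registry: {len(dog.muscles)} muscles "
      f"({sum(m.name.endswith('_l') for m in dog.muscles)} per side; "
      "the right side is a mirrored copy of the left)")

forelimb = build_forelimb_model()
print(f"\nleft forelimb evaluation model: {count_dofs(forelimb)} limb DOFs")
for stem, n in FORELIMB_DOF_BREAKDOWN.items():
    joint = forelimb.joint_by_name(f"{stem}_l")
    dofs = ", ".join(
        name for name, on in zip(("rx", "ry", "rz", "tx", "ty", "tz"), joint.dof_flags) if on
    )
    print(f"  {stem:9s} {n} DOFs ({dofs})")
print("\nThe forelimb total of 15 is the mobility needed for static-"
      "optimization convergence; the scapular translations reflect the "
      "muscle-sling suspension of the shoulder girdle.")
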