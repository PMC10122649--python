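"""Detect buried cavities and funnel geometry on a grid.

Two analytic test cases: a spherical cavity of radius 6 A (volume known in
closed form) and a 40 A conical funnel that narrows from a wide
cytoplasmic base to a tight lumenal tip, mimicking a substrate-delivery
crevice through a transmembrane domain.
"""

import numpy as np

import memstab
from memstab import fixtures as fx

frame = memstab.MembraneFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]), 15.0)

sphere = fx.make_cavity_model("sphere", {"radius": 6.0})
ps = memstab.detect_pockets(sphere, frame, spacing=0.5)
analytic = 4 / 3 * np.pi * 6**3
print(f"sphere: detected {ps.pockets[0].volume:.0f} A^3, analytic {analytic:.0f} A^3")

cone = fx.make_cavity_model("cone", {"length": 40.0, "base_radius": 8.0, "tip_radius": 2.0})
psc = memstab.detect_pockets(cone, frame, spacing=0.5)
fp = memstab.funnel_profile(cone, frame, psc.pockets[0])
print(f"cone: length {fp.length:.1f} A, funnel={fp.is_funnel} (Spearman {fp.spearman:.2f})")
print("radius vs depth (first 5 slabs, cytoplasmic side first):")
print(fp.radius_vs_depth.head().to_string(index=False))
# The funnel flag requires the slab radius to fall monotonically from the
# cytoplasmic toward the lumenal side of the membrane.
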