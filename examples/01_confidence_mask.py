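"""Mask low-confidence regions of a predicted structure before design.

Builds a seven-helix bundle whose pLDDT profile dips below 90 in two
stretches, then derives the set of positions where design is forbidden:
each sub-threshold run plus two flanking positions per side.
"""

import memstab
from memstab import fixtures as fx

bundle = fx.make_helix_bundle(seed=1, plddt_dips=[(40, 48, 70.0), (120, 126, 55.0)])
mask = memstab.build_mask(bundle.plddt, threshold=90, flank=2)

print(f"protein length: {mask.length}")
print(f"restricted positions ({len(mask.restricted)}): {sorted(mask.restricted)}")
print(f"designable positions: {len(memstab.designable_positions(mask))}")
# The two dips (40-48 and 120-126) each expand by 2 residues per side,
# so 38-50 and 118-128 are off-limits; everything else may be redesigned.
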