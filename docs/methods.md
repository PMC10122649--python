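# Methods

## Scope and model

memstab implements a one-step stabilization workflow for multi-spanning
membrane proteins from a predicted structure, under three assumptions:

1. the predicted backbone is reliable wherever per-residue confidence is
   high, so design can be restricted rather than re-predicted;
2. stabilizing substitutions are enriched among homologs, so a
   position-specific score matrix (PSSM) is a sound pre-filter;
3. per-mutation effects are approximately additive, so the optimal
   combination within a sequence space decomposes per position.

The workflow is: confidence mask → PSSM filter → membrane-aware energy →
threshold ladder → combinatorial selection. Companion modules provide
Kabsch superposition and grid-based cavity/funnel analysis.

## Confidence masking

Positions with pLDDT strictly below the threshold (default 90 on the
0–100 scale) are restricted. Each maximal sub-threshold run is expanded by
`flank` positions (default 2) on *each* side, clipped at the termini. The
symmetric per-side reading protects both boundaries of an uncertain
segment; restricting two positions total per stretch would leave one
boundary exposed for asymmetric dips. Files storing confidence on the 0–1
scale are detected (all B-factors ≤ 1) and rescaled ×100 on read;
fractional values co-occurring with values > 50 are rejected as a mixed
file rather than silently rescaled.

## PSSM construction and the phylogenetic filter

Per query-mapped column c and amino acid a,

    p(a|c) = (w(a,c) + α·q_a) / (Σ_b w(b,c) + α),   s(c,a) = log2(p/q_a)

in bits, with uniform background q (an observed-frequency background can
be supplied) and pseudocount α = 1. Gaps and non-standard residues
contribute nothing. Sequence weights follow the Henikoff & Henikoff
position-based scheme computed over the **unique** alignment rows,
normalized to mean 1. Operating on unique rows is a deliberate choice:
position-based weights alone dampen but do not exactly cancel the effect
of duplicated sequences, whereas collapsing exact duplicates makes the
profile strictly invariant to them — a property the test suite asserts to
1e-9. Mutations scoring strictly below 0 bits are eliminated; a score of
exactly 0 ("as expected under the background") is retained.

## Membrane energy surrogate

The per-mutation score is

    E = −λ1·s + λ2·w(z)·(1−b)·(H_wt − H_mut) + λ3·clash

* `s` — PSSM log-odds of the mutant (bits). λ1 = 1, so one bit of
  phylogenetic support is the energy unit.
* `w(z) = 1/(1+exp((|z|−h)/s))` — membrane depth weight; h = 15 Å
  hydrophobic half-thickness (a generic ER-like bilayer), s = 3 Å
  transition softness. The sigmoid gives the gradual cytoplasm↔membrane
  transition; it is exactly 0.5 at the slab boundary and symmetric in z.
* `b = min(1, N/24)` — burial from Cβ (Cα for Gly) neighbors within 10 Å;
  24 neighbors saturate. The lipophilicity reward `H_wt − H_mut`
  (Kyte–Doolittle) therefore acts only on lipid-exposed residues deep in
  the slab; λ2 = 0.5 keeps a 1-unit hydropathy gain worth half a bit.
* `clash = max(0, V_mut − V_wt − (1−b)·V_slack)/V_scale` — hard-sphere
  proxy with Zamyatnin residue volumes; V_slack = 40 Å³ of free volume at
  full exposure, V_scale = 20 Å³ per unit, λ3 = 1. No repacking is
  attempted: the backbone is rigid and sterics are centroid-level.

This is an explicitly labeled surrogate sharing the qualitative structure
of membrane-protein all-atom energy functions (depth- and burial-dependent
lipophilicity, gradual domain transition); it does not reproduce any
particular force field's values, and exact recovery of published design
compositions is a non-goal. All constants live in `EnergyParams`, are
config-exposed and are logged with every run. Mutations with E > 0 are
"not stabilizing" and eliminated.

The membrane frame is fitted as the first principal axis of the pooled
transmembrane Cα coordinates (centroid = slab center), signed from the
N-terminal end of the first TM range toward its C-terminal end; the
compartment on the positive side defaults to cytoplasmic and is a field of
the frame, since it is topology knowledge the structure alone cannot give.

## Design ladder and selection

K = 18 thresholds are evenly spaced from min(E) (strictest) to 0
(loosest; E > 0 was already eliminated). Even, data-dependent spacing is a
design choice — only the count is fixed — and both are configurable.
Spaces are nested by construction. Within a space, the additive model
makes the optimum the per-position lowest-E mutation (ties: alphabetical);
a seeded Monte-Carlo refinement pass exists for future non-additive terms
and is a deterministic no-op under additivity. Designs are named d1…d18 by
ladder index. Active-site positions are not explicitly protected — the
phylogenetic filter restrains them implicitly — but an exclusion list is
accepted.

## Superposition

Closed-form Kabsch SVD superposition over user-paired Cα residue ranges;
no internal sequence alignment is performed, because the pairing policy
for a domain comparison should be explicit. Fewer than 3 pairs or
rank-deficient (collinear) point sets are rejected. Reflections are
prevented (det R = +1). Insertion codes are rejected on read; altloc
keeps the highest occupancy, ties toward 'A'.

## Cavity detection

A cubic grid (default 1.0 Å; 0.5 Å for quantitative volumes) covers the
padded bounding box. Cells within vdW + probe (1.4 Å) of any atom are
occupied (Bondi radii by element). A free cell is a pocket cell when at
least 60% of 14 scan rays (6 axial + 8 corner diagonals) hit an occupied
cell before leaving the grid — this buriedness cutoff separates enclosed
cavities from bulk solvent concavities. Pocket cells are clustered by
26-connectivity; clusters under `min_cells` (default 10, the analogue of a
"pocket report size") are dropped; volume = n·spacing³. Side labels come
from the centroid projection on the membrane normal: beyond ±h/3 →
cytoplasmic/lumenal, else mid-membrane.

Funnel profiling projects pocket cells on the normal, reports the extent
(+1 cell) as length and the per-1 Å-slab equivalent circular radius
√(area/π); a pocket is a funnel when Spearman ρ ≤ −0.5 for radius ordered
from the cytoplasmic toward the lumenal side. Volume tracking re-detects
per frame and matches pockets greedily by nearest centroid (≤ 5 Å,
injective per frame) against each track's last-seen centroid, so an
identity survives single-frame dropouts; absent frames are recorded as NaN
in the volume-versus-time table.

Numerical behavior verified by the suite: halving the grid spacing moves an
analytic sphere volume by < 5%; volumes are recovered within 10% of closed
form at 0.5 Å spacing and are rigid-transform covariant to about one cell.

## Synthetic data

The generators define the study conditions and are first-class, tested
code:

* **Helix bundle** — 7 ideal α-helices × 30 residues (1.5 Å rise, 100°
  twist, Cα at 2.3 Å, pseudo-Cβ 1.53 Å further out) on a 10 Å circle,
  z-extent ≈ 45 Å, matching a multi-spanning TM domain's scale; pLDDT
  baseline 95 with configurable dips. Overlapping placements are rejected.
* **MSA** — 50 rows by default; planted positions substitute to their
  tolerated sets at rate 0.3, all other positions invariant (a background
  mutation rate is available). The planted truth is returned for recovery
  tests.
* **Cavity models** — pseudo-atom shells (sphere/cone/cylinder) whose
  atoms sit exactly vdW + probe outside the requested surface, so detected
  volumes are analytically checkable; multi-cavity models carve spherical
  voids from one solid lattice, which cannot create spurious inter-shell
  crevices. Frames apply seeded jitter, radial growth, or repetition.

What the fixtures do **not** emulate: real side-chain packing, lipids,
water, sequence-structure consistency (the bundle's sequence is random),
or correlated backbone motions. Passing tests therefore demonstrate the
correctness of the algorithms and their contracts, not predictive accuracy
on real proteins; real-structure validation consumes AlphaFold models and
deposited trajectories through the same interfaces.

## Determinism and reproducibility

All randomness flows through seeded NumPy generators; pipeline reruns with
the same inputs and seed are byte-identical for every output file. The run
manifest additionally records the command line, config snapshot, input
SHA-256 checksums, package version and a wall-clock timestamp — the
timestamp is the one field excluded from the byte-identity contract.

## Problem sizes

Default test and acceptance runs use the 210-residue bundle, 50-row
alignments, and grids of ≈0.2–0.4 M cells (0.5 Å spacing on ~25 Å
geometries); the full synthetic pipeline completes in well under a minute
on one CPU. These sizes were chosen as the smallest at which every
contract (nestedness, recovery, 10% volume accuracy) is meaningfully
exercised.

## Known limitations

* The energy surrogate has no electrostatics, hydrogen bonding, rotamer
  sampling or insertion energetics; rankings are qualitative.
* Burial via a fixed neighbor-count saturation (24 within 10 Å) is crude
  at chain termini and for peripheral helices.
* The slab membrane ignores curvature, leaflet asymmetry and hydrophobic
  mismatch.
* Grid buriedness with 14 rays can admit wide-mouthed concavities near
  the 0.6 cutoff; the cutoff and ray set are fixed by design for
  determinism.
* The confidence-flank width and the "two per side" reading are
  conventions; asymmetric alternatives are not implemented.
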