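"""Membrane-aware stability scoring.

A slab model of the bilayer (center, normal, half-thickness) drives a
depth-dependent lipophilicity reward that transitions smoothly from bulk
water to the hydrophobic core, gated by residue burial so that only
lipid-exposed positions feel it. A hard-sphere volume term penalizes
mutations too large for the local free volume. The total per-mutation
score is an explicit surrogate with the qualitative structure of
membrane-protein all-atom energy functions, not a re-implementation of one:

    E = -lam_pssm * pssm_score
        + lam_lipo * w(z) * (1 - b) * (H_wt - H_mut)
        + lam_clash * clash

with Kyte-Doolittle hydropathy H, depth weight w(z), burial b. Lower is
more stabilizing; E > 0 marks a mutation as not stabilizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._tables import KYTE_DOOLITTLE, RESIDUE_VOLUME
from .pssm import MutationCandidate
from .structio import StructureModel

__all__ = [
    "MembraneFrame",
    "EnergyParams",
    "EnergyBreakdown",
    "fit_membrane_frame",
    "depth_weight",
    "burial",
    "mutation_energy",
]


@dataclass
class MembraneFrame:
    """Slab model of the bilayer.

    ``normal`` is a unit vector; by the fitting convention it points from
    the leaflet holding the N-terminus of the first transmembrane range
    toward the other leaflet. ``positive_side`` names the compartment on
    the positive-projection side (used for pocket side labels).
    """

    center: np.ndarray
    normal: np.ndarray
    half_thickness: float = 15.0
    positive_side: str = "cytoplasmic"
    negative_side: str = "lumenal"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-9:
            self.normal = self.normal / norm
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")

    def depth(self, xyz: np.ndarray) -> float:
        """Signed projection of a point on the membrane normal (A)."""
        return float(np.dot(np.asarray(xyz, float) - self.center, self.normal))


def fit_membrane_frame(
    model: StructureModel,
    tm_residue_ranges: Sequence[tuple[int, int]],
    half_thickness: float = 15.0,
) -> MembraneFrame:
    """Fit the membrane slab from transmembrane helix residue ranges.

    The normal is the first principal axis of the pooled TM Calpha
    coordinates; the center is their centroid. The sign is fixed so the
    normal points from the first range's N-terminal end toward its
    C-terminal end.
    """
    if not tm_residue_ranges:
        raise ValueError("at least one transmembrane range is required")
    coords = []
    for start, end in tm_residue_ranges:
        nums = [n for n in range(start, end + 1)]
        ca = model.ca_coords(nums)
        if ca.shape[0] < 6:
            raise ValueError(f"TM range {start}-{end} has fewer than 6 Calpha atoms")
        coords.append(ca)
    X = np.vstack(coords)
    center = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - center)
    normal = Vt[0]
    first = tm_residue_ranges[0]
    head = model.ca_coords([first[0]])[0]
    tail = model.ca_coords([first[1]])[0]
    if np.dot(normal, tail - head) < 0:
        normal = -normal
    return MembraneFrame(center, normal, half_thickness)


def depth_weight(z_distance: float, frame: MembraneFrame, softness: float = 3.0) -> float:
    """Sigmoid membrane-depth weight in [0, 1]; 1 at the midplane, 0 in bulk water.

    ``w(z) = 1 / (1 + exp((|z| - h) / s))`` with h the hydrophobic
    half-thickness and s the transition softness (A). Exactly 0.5 at the
    slab boundary and symmetric about the midplane.
    """
    if softness <= 0:
        raise ValueError("softness must be positive")
    x = (abs(z_distance) - frame.half_thickness) / softness
    # guard exp overflow far in bulk water
    if x > 500:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


def _side_chain_anchor(model: StructureModel, index: int) -> np.ndarray:
    """CB coordinate of residue ``index`` (0-based), CA for glycine/CB-less."""
    res = model.residues[index]
    atom = res.atom("CB") or res.atom("CA")
    return np.asarray(atom.xyz, dtype=float)


def burial(model: StructureModel, position: int, radius: float = 10.0,
           n_max: int = 24) -> float:
    """Fractional burial in [0, 1] from side-chain neighbor counts.

    Counts CB atoms (CA for glycine) of other residues within ``radius`` of
    this residue's own CB/CA; ``n_max`` neighbors saturate to full burial.
    """
    idx = model.resnums.index(position)
    anchors = np.array(
        [_side_chain_anchor(model, i) for i in range(len(model.residues))]
    )
    tree = cKDTree(anchors)
    neighbors = tree.query_ball_point(anchors[idx], r=radius)
    n = len([j for j in neighbors if j != idx])
    return min(1.0, n / float(n_max))


@dataclass
class EnergyParams:
    """Tunable constants of the stability surrogate (arbitrary energy units)."""

    lam_pssm: float = 1.0
    lam_lipo: float = 0.5
    lam_clash: float = 1.0
    softness: float = 3.0       # A, slab transition width
    burial_radius: float = 10.0  # A, neighbor-count sphere
    n_max: int = 24              # neighbors at full burial
    vol_slack: float = 40.0      # A^3 of free volume available at full exposure
    vol_scale: float = 20.0      # A^3 per clash energy unit

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "lam_pssm", "lam_lipo", "lam_clash", "softness",
            "burial_radius", "n_max", "vol_slack", "vol_scale")}


@dataclass
class EnergyBreakdown:
    """Additive decomposition of a mutation's score, for audit output."""

    pssm_term: float
    lipo_term: float
    clash_term: float
    depth_weight: float
    burial: float

    @property
    def total(self) -> float:
        return self.pssm_term + self.lipo_term + self.clash_term


def mutation_energy(
    model: StructureModel,
    candidate: MutationCandidate,
    frame: MembraneFrame,
    params: EnergyParams | None = None,
    _burial_value: float | None = None,
) -> EnergyBreakdown:
    """Score one mutation; lower is more stabilizing, E > 0 is destabilizing.

    The lipophilicity term rewards hydrophobicity gains only where the
    residue is both deep in the slab (w close to 1) and lipid-exposed
    (burial close to 0); the clash term penalizes side-chain volume
    exceeding the free volume implied by burial.
    """
    if params is None:
        params = EnergyParams()
    wt, mut = candidate.wt_aa, candidate.mut_aa
    if wt not in KYTE_DOOLITTLE or mut not in KYTE_DOOLITTLE:
        raise ValueError(f"unknown residue type in {wt}->{mut}")
    idx = model.resnums.index(candidate.position)
    ca = np.asarray(model.residues[idx].atom("CA").xyz, float)
    z = frame.depth(ca)
    w = depth_weight(z, frame, params.softness)
    b = _burial_value if _burial_value is not None else burial(
        model, candidate.position, params.burial_radius, params.n_max
    )
    pssm_term = -params.lam_pssm * candidate.pssm_score
    lipo_term = (
        params.lam_lipo * w * (1.0 - b)
        * (KYTE_DOOLITTLE[wt] - KYTE_DOOLITTLE[mut])
    )
    free_vol = RESIDUE_VOLUME[wt] + (1.0 - b) * params.vol_slack
    clash = max(0.0, RESIDUE_VOLUME[mut] - free_vol) / params.vol_scale
    clash_term = params.lam_clash * clash
    return EnergyBreakdown(pssm_term, lipo_term, clash_term, w, b)
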