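"""Deterministic synthetic inputs: helix bundles, homolog MSAs, cavity models.

Everything the workflow consumes — a predicted structure with per-residue
confidence, a homolog alignment with planted tolerated substitutions, and
cavity-bearing pseudo-atom models with trajectory frames — is generated
here from a seed, so the package builds and tests without any downloads.
Geometry is Calpha/pseudo-Cbeta only; that resolution is sufficient for
every operation in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._tables import AMINO_ACIDS, ONE_TO_THREE
from .structio import (
    Alignment,
    Atom,
    FrameSeries,
    Residue,
    StructureModel,
    write_structure,
)

__all__ = [
    "make_helix_bundle",
    "make_msa",
    "make_cavity_model",
    "make_multi_cavity_model",
    "make_frames",
    "write_alignment_fasta",
    "write_frames_pdb",
    "write_fixture_suite",
]

HELIX_RISE = 1.5          # A per residue along the axis
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # A, Calpha distance from the helix axis
CB_OFFSET = 1.53          # A, pseudo-Cbeta radial offset beyond Calpha

# shell atoms sit at cavity radius + carbon vdW (1.7) + probe (1.4)
SHELL_STANDOFF = 3.1
SHELL_POINT_SPACING = 1.2


def make_helix_bundle(
    n_helices: int = 7,
    residues_per_helix: int = 30,
    rise: float = HELIX_RISE,
    bundle_radius: float = 10.0,
    plddt_baseline: float = 95.0,
    plddt_dips: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
    sequence: str | None = None,
    antiparallel: bool = False,
) -> StructureModel:
    """Ideal alpha-helix bundle, helices parallel to z on a circle.

    Each residue carries a Calpha on ideal helical geometry and a pseudo-
    Cbeta pointing outward from its helix axis. B-factors (pLDDT) follow
    ``plddt_baseline`` with ``plddt_dips`` as (start, end, value) 1-based
    closed intervals over the whole bundle.
    """
    if n_helices < 1:
        raise ValueError("need at least one helix")
    if n_helices > 1:
        chord = 2.0 * bundle_radius * math.sin(math.pi / n_helices)
        if chord < 2.0 * (HELIX_RADIUS + 1.0):
            raise ValueError(
                f"bundle radius {bundle_radius} too small: helices would overlap"
            )
    rng = np.random.default_rng(seed)
    total = n_helices * residues_per_helix
    if sequence is None:
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=total))
    if len(sequence) != total:
        raise ValueError("sequence length != n_helices * residues_per_helix")
    plddt = np.full(total, float(plddt_baseline))
    for start, end, value in plddt_dips or []:
        plddt[start - 1 : end] = value

    residues: list[Residue] = []
    resnum = 0
    for h in range(n_helices):
        phi = 2.0 * math.pi * h / n_helices if n_helices > 1 else 0.0
        ax = bundle_radius * math.cos(phi) if n_helices > 1 else 0.0
        ay = bundle_radius * math.sin(phi) if n_helices > 1 else 0.0
        reversed_helix = antiparallel and h % 2 == 1
        for i in range(residues_per_helix):
            resnum += 1
            theta = math.radians(HELIX_TWIST * i)
            # antiparallel helices run top-down through the same z slab
            z = rise * (residues_per_helix - 1 - i) if reversed_helix else rise * i
            ca = (
                ax + HELIX_RADIUS * math.cos(theta),
                ay + HELIX_RADIUS * math.sin(theta),
                z,
            )
            cb = (
                ax + (HELIX_RADIUS + CB_OFFSET) * math.cos(theta),
                ay + (HELIX_RADIUS + CB_OFFSET) * math.sin(theta),
                z,
            )
            aa = sequence[resnum - 1]
            atoms = [Atom("CA", ca, plddt[resnum - 1])]
            if aa != "G":
                atoms.append(Atom("CB", cb, plddt[resnum - 1]))
            residues.append(Residue(resnum, aa, tuple(atoms)))
    return StructureModel("A", residues, plddt)


def tm_ranges_for_bundle(n_helices: int, residues_per_helix: int) -> list[tuple[int, int]]:
    """Residue ranges of each helix in a bundle built by make_helix_bundle."""
    return [
        (h * residues_per_helix + 1, (h + 1) * residues_per_helix)
        for h in range(n_helices)
    ]


def make_msa(
    target_sequence: str,
    n_rows: int = 50,
    tolerated: dict[int, str] | None = None,
    tolerated_rate: float = 0.3,
    mutation_rate: float = 0.0,
    seed: int = 0,
    query_id: str = "query",
) -> tuple[Alignment, dict[int, str]]:
    """Ungapped homolog alignment with planted tolerated substitutions.

    ``tolerated`` maps 1-based positions to the amino acids homologs may
    carry there besides the wild type; those positions substitute at
    ``tolerated_rate``. All other positions substitute uniformly at
    ``mutation_rate`` (invariant by default). Row 0 is the unmodified
    target. Returns the alignment and the planted truth.
    """
    if n_rows < 1:
        raise ValueError("need at least one row")
    tolerated = dict(tolerated or {})
    for pos, aas in tolerated.items():
        wt = target_sequence[pos - 1]
        alts = [a for a in aas if a != wt]
        if not alts and tolerated_rate > 0:
            raise ValueError(
                f"position {pos}: tolerated set contains only the wild type"
            )
        tolerated[pos] = "".join(alts)
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = [(query_id, target_sequence)]
    others = [a for a in AMINO_ACIDS]
    for r in range(1, n_rows):
        seq = list(target_sequence)
        for pos in range(1, len(target_sequence) + 1):
            if pos in tolerated:
                if tolerated[pos] and rng.random() < tolerated_rate:
                    seq[pos - 1] = tolerated[pos][rng.integers(len(tolerated[pos]))]
            elif mutation_rate > 0 and rng.random() < mutation_rate:
                choices = [a for a in others if a != target_sequence[pos - 1]]
                seq[pos - 1] = choices[rng.integers(len(choices))]
        rows.append((f"homolog_{r}", "".join(seq)))
    return Alignment(rows, 0), tolerated


# ---------------------------------------------------------------------------
# cavity models


def _fibonacci_sphere(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    n = max(8, int(math.ceil(4.0 * math.pi * radius ** 2 / spacing ** 2)))
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    pts = np.column_stack(
        [
            radius * np.sin(phi) * np.cos(theta),
            radius * np.sin(phi) * np.sin(theta),
            radius * np.cos(phi),
        ]
    )
    return pts + center


def _ring(center_z: float, radius: float, spacing: float) -> np.ndarray:
    if radius < spacing / 2.0:
        return np.array([[0.0, 0.0, center_z]])
    n = max(6, int(math.ceil(2.0 * math.pi * radius / spacing)))
    theta = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full(n, center_z)]
    )


def _disk(center_z: float, radius: float, spacing: float) -> np.ndarray:
    rings = [np.array([[0.0, 0.0, center_z]])]
    r = spacing
    while r <= radius:
        rings.append(_ring(center_z, r, spacing))
        r += spacing
    return np.vstack(rings)


def make_cavity_model(
    shape: str,
    dimensions: dict[str, float],
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    standoff: float = SHELL_STANDOFF,
    point_spacing: float = SHELL_POINT_SPACING,
) -> StructureModel:
    """Pseudo-atom shell enclosing a cavity of the requested geometry.

    Shapes: ``sphere`` (radius), ``cone`` (length along z, base_radius at
    +z, tip_radius at -z) and ``cylinder`` (length, radius). Shell atoms
    are carbons placed ``standoff`` (vdW + probe) outside the cavity
    surface so the detected void matches the requested dimensions; cones
    and cylinders are capped at both ends.
    """
    if shape == "sphere":
        r = float(dimensions["radius"])
        if r <= 0:
            raise ValueError("sphere radius must be positive")
        pts = _fibonacci_sphere(np.zeros(3), r + standoff, point_spacing)
    elif shape in ("cone", "cylinder"):
        length = float(dimensions["length"])
        if length <= 0:
            raise ValueError("length must be positive")
        if shape == "cone":
            r_base = float(dimensions["base_radius"])
            r_tip = float(dimensions.get("tip_radius", 1.5))
        else:
            r_base = r_tip = float(dimensions["radius"])
        if min(r_base, r_tip) <= 0:
            raise ValueError("radii must be positive")
        layers = []
        # walls extend `standoff` beyond both ends so the caps sit one full
        # vdW+probe distance past the cavity end planes and do not truncate it
        z = -length / 2.0 - standoff
        while z <= length / 2.0 + standoff + 1e-9:
            zc = min(max(z, -length / 2.0), length / 2.0)
            frac = (zc + length / 2.0) / length
            r_cav = r_tip + (r_base - r_tip) * frac
            layers.append(_ring(z, r_cav + standoff, point_spacing))
            z += point_spacing
        for zc, rc in (
            (-length / 2.0 - standoff, r_tip + standoff),
            (-length / 2.0 - standoff - point_spacing, r_tip + standoff),
            (length / 2.0 + standoff, r_base + standoff),
            (length / 2.0 + standoff + point_spacing, r_base + standoff),
        ):
            layers.append(_disk(zc, rc, point_spacing))
        pts = np.vstack(layers)
    else:
        raise ValueError(f"unknown cavity shape {shape!r}")
    pts = pts + np.asarray(center, dtype=float)
    return _points_to_model(pts)


def make_multi_cavity_model(
    voids: list[tuple[float, tuple[float, float, float]]],
    lattice_spacing: float = 1.2,
    margin: float = 4.0,
    standoff: float = SHELL_STANDOFF,
) -> StructureModel:
    """Several spherical voids carved out of one solid pseudo-atom block.

    ``voids`` is a list of (radius, center). Using a single filled lattice
    rather than separate shells avoids spurious buried crevices between
    neighboring cavities; the block extends ``margin`` (A) beyond every
    void surface.
    """
    if not voids:
        raise ValueError("need at least one void")
    centers = np.array([c for _, c in voids], dtype=float)
    radii = np.array([r for r, _ in voids], dtype=float)
    if (radii <= 0).any():
        raise ValueError("void radii must be positive")
    lo = (centers - (radii + standoff + margin)[:, None]).min(axis=0)
    hi = (centers + (radii + standoff + margin)[:, None]).max(axis=0)
    axes = [np.arange(lo[d], hi[d] + lattice_spacing, lattice_spacing) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    keep = np.ones(pts.shape[0], dtype=bool)
    for r, c in zip(radii, centers):
        keep &= np.linalg.norm(pts - c, axis=1) >= r + standoff
    return _points_to_model(pts[keep])


def _points_to_model(pts: np.ndarray) -> StructureModel:
    residues = [
        Residue(i + 1, "G", (Atom("CA", tuple(p), 99.0),))
        for i, p in enumerate(pts)
    ]
    return StructureModel("A", residues, np.full(len(residues), 99.0))


def make_frames(
    model: StructureModel,
    n_frames: int = 10,
    motion: str = "jitter",
    sigma: float = 0.1,
    growth_rate: float = 0.0,
    seed: int = 0,
) -> FrameSeries:
    """Trajectory frames from a model: coordinate jitter or radial growth.

    ``jitter`` adds i.i.d. Gaussian noise (sigma, A) to every coordinate;
    ``grow`` scales coordinates radially about the centroid by
    ``1 + growth_rate * k`` for frame k (a cavity shell's inner radius then
    grows as ``scale * r_shell - standoff``); ``static`` repeats the model.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    base = model.atom_coords()
    centroid = base.mean(axis=0)
    frames = []
    for k in range(n_frames):
        if motion == "static":
            coords = base.copy()
        elif motion == "jitter":
            coords = base + rng.normal(0.0, sigma, size=base.shape)
        elif motion == "grow":
            scale = 1.0 + growth_rate * k
            coords = centroid + (base - centroid) * scale
        else:
            raise ValueError(f"unknown motion model {motion!r}")
        frames.append(coords)
    return FrameSeries(frames, times=[float(k) for k in range(n_frames)])


# ---------------------------------------------------------------------------
# file writers


def write_alignment_fasta(alignment: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in alignment.sequences:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_frames_pdb(model: StructureModel, frames: FrameSeries, path: str | Path) -> None:
    """Write a FrameSeries as a multi-model PDB sharing the model's topology."""
    with open(path, "w") as fh:
        for mi, coords in enumerate(frames.frames, start=1):
            fh.write(f"MODEL     {mi:4d}\n")
            serial = 0
            k = 0
            for res, conf in zip(model.residues, model.plddt):
                for a in res.atoms:
                    serial += 1
                    x, y, z = coords[k]
                    k += 1
                    fh.write(
                        f"ATOM  {serial:5d} {a.name:^4s}{ONE_TO_THREE[res.aa]:>4s} "
                        f"A{res.resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{1.00:6.2f}{conf:6.2f}           {a.element:>2s}\n"
                    )
            fh.write("ENDMDL\n")
        fh.write("END\n")


@dataclass
class FixtureSuite:
    """Paths of a generated on-disk fixture set."""

    bundle_pdb: Path
    alignment_fasta: Path
    sphere_pdb: Path
    cone_pdb: Path
    frames_pdb: Path
    planted: dict[int, str] = field(default_factory=dict)


def write_fixture_suite(outdir: str | Path, seed: int = 0) -> FixtureSuite:
    """Emit the standard named fixture set (bundle, MSA, cavities, frames)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = make_helix_bundle(
        seed=seed, plddt_dips=[(40, 48, 70.0), (120, 126, 55.0)]
    )
    tolerated = {10: "AS", 75: "ILV", 150: "FY"}
    # keep planted substitutions distinct from each wild type
    tolerated = {
        pos: "".join(a for a in aas if a != bundle.sequence[pos - 1]) or "A"
        for pos, aas in tolerated.items()
    }
    msa, planted = make_msa(bundle.sequence, n_rows=50, tolerated=tolerated, seed=seed)
    sphere = make_cavity_model("sphere", {"radius": 6.0})
    cone = make_cavity_model("cone", {"length": 40.0, "base_radius": 8.0, "tip_radius": 2.0})
    frames = make_frames(sphere, n_frames=5, motion="jitter", sigma=0.1, seed=seed)

    suite = FixtureSuite(
        bundle_pdb=outdir / "bundle.pdb",
        alignment_fasta=outdir / "alignment.fasta",
        sphere_pdb=outdir / "cavity_sphere.pdb",
        cone_pdb=outdir / "cavity_cone.pdb",
        frames_pdb=outdir / "frames.pdb",
        planted=planted,
    )
    write_structure(bundle, suite.bundle_pdb)
    write_alignment_fasta(msa, suite.alignment_fasta)
    write_structure(sphere, suite.sphere_pdb)
    write_structure(cone, suite.cone_pdb)
    write_frames_pdb(sphere, frames, suite.frames_pdb)
    return suite
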