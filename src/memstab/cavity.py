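"""Grid-based detection of buried cavities and funnel geometry.

A cubic grid is laid over the structure; cells outside every atom's van der
Waals + probe radius are solvent-accessible, and those enclosed by protein
— judged by the fraction of 14 fixed scan rays (6 axial, 8 diagonal) that
hit protein before leaving the grid — are pocket cells. 26-connected
clusters above a minimum size are reported as pockets with volumes
(cells x spacing^3), membrane-side labels from the slab frame, and can be
tracked across trajectory frames by centroid proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from ._tables import vdw_radius
from .membrane import MembraneFrame
from .structio import FrameSeries, StructureModel

__all__ = [
    "Pocket",
    "PocketSet",
    "FunnelProfile",
    "PocketSeries",
    "detect_pockets",
    "funnel_profile",
    "track_volumes",
    "pocket_cells_to_pdb",
]

# 6 axial + 8 corner-diagonal scan directions
SCAN_DIRECTIONS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    (-1, 1, 1), (-1, 1, -1), (-1, -1, 1), (-1, -1, -1),
]


@dataclass
class Pocket:
    """One 26-connected cluster of buried, solvent-free grid cells."""

    cells: np.ndarray          # (n, 3) cell-center coordinates, A
    volume: float              # A^3, n_cells * spacing^3
    centroid: np.ndarray
    side_label: str            # cytoplasmic | mid-membrane | lumenal
    frame_index: int = 0

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]


@dataclass
class PocketSet:
    pockets: list[Pocket]
    spacing: float
    frame_index: int = 0

    def __len__(self) -> int:
        return len(self.pockets)


def _grid_axes(coords: np.ndarray, radii: np.ndarray, probe: float,
               spacing: float, pad: float = 2.0) -> list[np.ndarray]:
    margin = radii.max() + probe + pad
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    return [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]


def _occupancy(coords: np.ndarray, radii: np.ndarray, axes, probe: float) -> np.ndarray:
    nx, ny, nz = (len(a) for a in axes)
    X, Y, Z = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    occ = np.zeros(centers.shape[0], dtype=bool)
    cell_tree = cKDTree(centers)
    for r in np.unique(radii):
        idx = np.where(radii == r)[0]
        hits = cell_tree.query_ball_point(coords[idx], r + probe)
        for h in hits:
            occ[h] = True
    return occ.reshape(nx, ny, nz)


def _blocked_fraction(occ: np.ndarray) -> np.ndarray:
    """Per-cell fraction of the 14 scan rays that hit an occupied cell."""
    blocked_count = np.zeros(occ.shape, dtype=np.int8)
    n_steps = max(occ.shape)
    for dx, dy, dz in SCAN_DIRECTIONS:
        # reach[i] == True iff some occupied cell lies along (dx,dy,dz) from i;
        # the reach | shift(reach) recurrence doubles the covered span per pass
        reach = occ.copy()
        for _ in range(n_steps):
            new = reach | _shift(reach, dx, dy, dz)
            if np.array_equal(new, reach):
                break
            reach = new
        blocked_count += reach
    return blocked_count / float(len(SCAN_DIRECTIONS))


def _shift(a: np.ndarray, dx: int, dy: int, dz: int) -> np.ndarray:
    """Shift boolean grid by one step opposite to the ray direction.

    ``out[i] = a[i + d]`` so that iterating propagates occupancy toward the
    ray origin (False past the boundary)."""
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, d in enumerate((dx, dy, dz)):
        if d == 1:
            dst[axis] = slice(0, -1)
            src[axis] = slice(1, None)
        elif d == -1:
            dst[axis] = slice(1, None)
            src[axis] = slice(0, -1)
    out[tuple(dst)] = a[tuple(src)]
    return out


def detect_pockets(
    model: StructureModel,
    frame: MembraneFrame,
    spacing: float = 1.0,
    probe: float = 1.4,
    min_cells: int = 10,
    buriedness: float = 0.6,
    frame_index: int = 0,
) -> PocketSet:
    """Detect buried solvent-free cavities on a cubic grid.

    Cells outside all atom vdW+probe spheres with a blocked-ray fraction
    >= ``buriedness`` are clustered by 26-connectivity; clusters of at
    least ``min_cells`` cells are returned sorted by volume, largest first.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    atoms = [(a.xyz, a.element) for r in model.residues for a in r.atoms]
    if not atoms:
        raise ValueError("model has no atoms")
    coords = np.array([xyz for xyz, _ in atoms], dtype=float)
    radii = np.array([vdw_radius(el) for _, el in atoms], dtype=float)
    axes = _grid_axes(coords, radii, probe, spacing)
    occ = _occupancy(coords, radii, axes, probe)
    frac = _blocked_fraction(occ)
    pocket_cells = (~occ) & (frac >= buriedness)
    labels, n_clusters = ndimage.label(pocket_cells, structure=np.ones((3, 3, 3)))
    pockets: list[Pocket] = []
    for lbl in range(1, n_clusters + 1):
        idx = np.argwhere(labels == lbl)
        if idx.shape[0] < min_cells:
            continue
        cells = np.column_stack(
            [axes[d][idx[:, d]] for d in range(3)]
        )
        centroid = cells.mean(axis=0)
        pockets.append(
            Pocket(
                cells=cells,
                volume=idx.shape[0] * spacing ** 3,
                centroid=centroid,
                side_label=_side_label(centroid, frame),
                frame_index=frame_index,
            )
        )
    pockets.sort(key=lambda p: -p.volume)
    return PocketSet(pockets, spacing, frame_index)


def _side_label(centroid: np.ndarray, frame: MembraneFrame) -> str:
    z = frame.depth(centroid)
    third = frame.half_thickness / 3.0
    if z > third:
        return frame.positive_side
    if z < -third:
        return frame.negative_side
    return "mid-membrane"


@dataclass
class FunnelProfile:
    """Pocket extent along the membrane normal and its radius-depth profile."""

    length: float                      # A along the normal
    radius_vs_depth: pd.DataFrame      # columns: depth (A, signed), radius (A)
    is_funnel: bool
    spearman: float


def funnel_profile(
    model: StructureModel,
    frame: MembraneFrame,
    pocket: Pocket,
    min_cells: int = 10,
    slab: float = 1.0,
) -> FunnelProfile:
    """Per-slab equivalent circular radius of a pocket along the normal.

    The pocket is a funnel when the radius decreases monotonically (Spearman
    rank correlation <= -0.5) from the cytoplasmic toward the lumenal side.
    """
    if pocket.n_cells < min_cells:
        raise ValueError(f"pocket has {pocket.n_cells} cells, need >= {min_cells}")
    proj = (pocket.cells - frame.center) @ frame.normal
    spacing = _infer_spacing(pocket.cells)
    length = float(proj.max() - proj.min()) + spacing
    # slabs ordered cytoplasmic (positive projection) -> lumenal
    edges = np.arange(proj.min(), proj.max() + slab, slab)
    rows = []
    for lo in edges[::-1]:
        n = int(((proj >= lo) & (proj < lo + slab)).sum())
        if n == 0:
            continue
        area = n * spacing ** 3 / slab
        rows.append({"depth": lo + slab / 2.0, "radius": float(np.sqrt(area / np.pi))})
    table = pd.DataFrame(rows, columns=["depth", "radius"])
    if len(table) >= 3 and table["radius"].nunique() > 1:
        rho = float(spearmanr(np.arange(len(table)), table["radius"]).statistic)
    else:
        rho = 0.0
    return FunnelProfile(length, table, rho <= -0.5, rho)


def _infer_spacing(cells: np.ndarray) -> float:
    for d in range(3):
        vals = np.unique(np.round(cells[:, d], 6))
        if len(vals) > 1:
            return float(np.min(np.diff(vals)))
    return 1.0


@dataclass
class PocketSeries:
    """Pockets matched across trajectory frames by centroid proximity."""

    per_frame: list[PocketSet]
    volume_vs_time: pd.DataFrame   # index: frame, columns: pocket id, A^3; NaN = absent
    mean_volumes: dict[int, float] = field(default_factory=dict)


def track_volumes(
    model: StructureModel,
    frames: FrameSeries,
    frame: MembraneFrame,
    match_radius: float = 5.0,
    **detector_params,
) -> PocketSeries:
    """Run pocket detection on every frame and match pockets through time.

    Matching is greedy nearest-centroid between consecutive frames within
    ``match_radius`` (A) and injective per frame; a pocket absent in a frame
    is recorded as NaN in the volume table.
    """
    per_frame: list[PocketSet] = []
    records: list[dict[int, float]] = []
    next_id = 0
    tracks: dict[int, Pocket] = {}  # id -> last observed pocket
    for fi, coords in enumerate(frames.frames):
        m = model.with_coordinates(coords)
        ps = detect_pockets(m, frame, frame_index=fi, **detector_params)
        per_frame.append(ps)
        assigned: dict[int, float] = {}
        ids_taken: set[int] = set()
        # greedy: smallest centroid distance first, against last-seen centroids
        pairs = sorted(
            (
                (np.linalg.norm(p.centroid - q.centroid), pid, j)
                for pid, q in tracks.items()
                for j, p in enumerate(ps.pockets)
            ),
            key=lambda t: t[0],
        )
        matched_j: set[int] = set()
        for dist, pid, j in pairs:
            if dist > match_radius or pid in ids_taken or j in matched_j:
                continue
            ids_taken.add(pid)
            matched_j.add(j)
            assigned[pid] = ps.pockets[j].volume
            tracks[pid] = ps.pockets[j]
        for j, p in enumerate(ps.pockets):
            if j not in matched_j:
                assigned[next_id] = p.volume
                tracks[next_id] = p
                next_id += 1
        records.append(assigned)
    all_ids = sorted({pid for rec in records for pid in rec})
    table = pd.DataFrame(
        [{pid: rec.get(pid, np.nan) for pid in all_ids} for rec in records],
        index=pd.RangeIndex(len(records), name="frame"),
    )
    means = {pid: float(table[pid].mean()) for pid in all_ids}
    return PocketSeries(per_frame, table, means)


def pocket_cells_to_pdb(pockets: PocketSet, path) -> None:
    """Write pocket grid cells as pseudo-atom HETATM records for visualization."""
    with open(path, "w") as fh:
        serial = 1
        for pid, p in enumerate(pockets.pockets, start=1):
            for x, y, z in p.cells:
                fh.write(
                    f"HETATM{serial:5d}  C   PKT {chr(64 + min(pid, 26))}{pid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
                serial += 1
        fh.write("END\n")
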