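"""Structure, alignment and trajectory I/O plus rigid-body superposition.

Structures are read from PDB or mmCIF with per-residue confidence (pLDDT)
taken from the B-factor column, following the AlphaFold2 convention. Files
written on the 0-1 scale are rescaled to 0-100 on read so that a single
internal scale is used everywhere. Superposition is the closed-form Kabsch
least-squares fit over user-paired Calpha ranges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import AlignIO

from ._tables import THREE_TO_ONE, ONE_TO_THREE

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "Alignment",
    "FrameSeries",
    "read_structure",
    "write_structure",
    "read_alignment",
    "superpose",
    "kabsch",
    "read_frames",
]


class StructureError(ValueError):
    """Raised for unusable structure, alignment or trajectory input."""


@dataclass(frozen=True)
class Atom:
    name: str
    xyz: tuple[float, float, float]
    bfactor: float
    element: str = "C"


@dataclass(frozen=True)
class Residue:
    resnum: int
    aa: str
    atoms: tuple[Atom, ...]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """A single protein chain: ordered residues, coordinates and confidence.

    ``plddt`` is always stored on the 0-100 scale; ``sequence`` is the
    one-letter sequence derived from the residues. Residue numbers are
    1-based as in the source file and strictly increasing.
    """

    chain_id: str
    residues: list[Residue]
    plddt: np.ndarray
    sequence: str = field(default="")

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError("structure has no residues")
        nums = [r.resnum for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise StructureError("residue numbers must be strictly increasing")
        self.plddt = np.asarray(self.plddt, dtype=float)
        if len(self.plddt) != len(self.residues):
            raise StructureError("plddt length must equal residue count")
        if ((self.plddt < 0) | (self.plddt > 100)).any():
            raise StructureError("plddt values must lie in [0, 100]")
        for r in self.residues:
            if r.atom("CA") is None:
                raise StructureError(f"residue {r.resnum} lacks a CA atom")
        if not self.sequence:
            self.sequence = "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def resnums(self) -> list[int]:
        return [r.resnum for r in self.residues]

    def residue_by_number(self, resnum: int) -> Residue:
        for r in self.residues:
            if r.resnum == resnum:
                return r
        raise KeyError(f"no residue numbered {resnum}")

    def ca_coords(self, resnums: Iterable[int] | None = None) -> np.ndarray:
        """Calpha coordinates, optionally for a subset of residue numbers."""
        if resnums is None:
            res = self.residues
        else:
            res = [self.residue_by_number(n) for n in resnums]
        return np.array([r.atom("CA").xyz for r in res], dtype=float)

    def atom_coords(self) -> np.ndarray:
        return np.array(
            [a.xyz for r in self.residues for a in r.atoms], dtype=float
        )

    def with_coordinates(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model with all atom coordinates replaced (same order)."""
        coords = np.asarray(coords, dtype=float)
        n_atoms = sum(len(r.atoms) for r in self.residues)
        if coords.shape != (n_atoms, 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} != ({n_atoms}, 3)"
            )
        new_res = []
        k = 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(Atom(a.name, tuple(coords[k]), a.bfactor, a.element))
                k += 1
            new_res.append(Residue(r.resnum, r.aa, tuple(atoms)))
        return StructureModel(self.chain_id, new_res, self.plddt.copy())


@dataclass
class Alignment:
    """A homolog multiple sequence alignment anchored on a design target.

    ``column_map`` maps 1-based alignment columns (non-gap in the query row)
    to 1-based query residue numbers.
    """

    sequences: list[tuple[str, str]]
    query_index: int
    column_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise StructureError("alignment rows have unequal lengths")
        if not (0 <= self.query_index < len(self.sequences)):
            raise StructureError("query_index out of range")
        if not self.column_map:
            self.column_map = _build_column_map(self.query_sequence_aligned)

    @property
    def query_sequence_aligned(self) -> str:
        return self.sequences[self.query_index][1]

    @property
    def query_sequence(self) -> str:
        return self.query_sequence_aligned.replace("-", "")

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1])


def _build_column_map(aligned_query: str) -> dict[int, int]:
    cmap: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(aligned_query, start=1):
        if ch != "-":
            res += 1
            cmap[col] = res
    return cmap


@dataclass
class FrameSeries:
    """Ordered coordinate snapshots sharing one topology."""

    frames: list[np.ndarray]
    times: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("frame series is empty")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape:
                raise StructureError("frames differ in atom count")
            if np.isnan(f).any():
                raise StructureError("frame contains NaN coordinates")
        if self.times is not None:
            if len(self.times) != len(self.frames):
                raise StructureError("times length != frame count")
            if any(b < a for a, b in zip(self.times, self.times[1:])):
                raise StructureError("times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# structure reading / writing


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved toward altloc 'A'
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "A"))[0]


def read_structure(path: str | Path, chain: str | None = None) -> StructureModel:
    """Read one chain of a PDB or mmCIF file into a :class:`StructureModel`.

    pLDDT is taken from the Calpha B-factor. If every B-factor in the chain
    is <= 1.0 the file uses the 0-1 dialect and values are multiplied by 100.
    Residues without a Calpha are dropped with a warning; insertion codes
    are rejected.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0 or len(st[0]) == 0:
        raise StructureError(f"{path}: no models/chains (zero ATOM records?)")
    model = st[0]
    if chain is None:
        ch = model[0]
    else:
        ch = None
        for c in model:
            if c.name == chain:
                ch = c
                break
        if ch is None:
            raise StructureError(f"{path}: chain {chain!r} not found")
    residues: list[Residue] = []
    bfactors: list[float] = []
    for res in ch:
        if res.het_flag == "W" or res.name == "HOH":
            continue
        aa = THREE_TO_ONE.get(res.name)
        if aa is None:
            continue
        if res.seqid.icode not in ("", " ", "\x00"):
            raise StructureError(
                f"{path}: insertion code at residue {res.seqid.num}{res.seqid.icode}"
            )
        by_name: dict[str, list[gemmi.Atom]] = {}
        for at in res:
            by_name.setdefault(at.name, []).append(at)
        atoms = []
        for name, variants in by_name.items():
            at = _pick_altloc(variants)
            atoms.append(
                Atom(
                    name,
                    (at.pos.x, at.pos.y, at.pos.z),
                    at.b_iso,
                    at.element.name or "C",
                )
            )
        ca = next((a for a in atoms if a.name == "CA"), None)
        if ca is None:
            logger.warning(
                "%s: residue %s %d has no CA, skipped", path, res.name, res.seqid.num
            )
            continue
        residues.append(Residue(res.seqid.num, aa, tuple(atoms)))
        bfactors.append(ca.bfactor)
    if not residues:
        raise StructureError(f"{path}: chain {ch.name!r} has no usable residues")
    b = np.array(bfactors, dtype=float)
    if b.max() <= 1.0:
        b = b * 100.0
    elif b.max() > 50.0 and ((b > 0) & (b < 1.0)).any():
        raise StructureError(
            f"{path}: mixed confidence scales (values both <1 and >50)"
        )
    return StructureModel(ch.name, residues, b)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a single-chain PDB file (B-factor = pLDDT)."""
    st = gemmi.Structure()
    st.name = "memstab"
    gm = gemmi.Model("1")
    gc = gemmi.Chain(model.chain_id or "A")
    for res, conf in zip(model.residues, model.plddt):
        gr = gemmi.Residue()
        gr.name = ONE_TO_THREE[res.aa]
        gr.seqid = gemmi.SeqId(res.resnum, " ")
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.pos = gemmi.Position(*a.xyz)
            ga.b_iso = float(conf)
            ga.occ = 1.0
            ga.element = gemmi.Element(a.element)
            gr.add_atom(ga)
        gc.add_residue(gr)
    gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# alignment reading


def read_alignment(path: str | Path, query_id: str) -> Alignment:
    """Read an aligned FASTA file; ``query_id`` names the design target row."""
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise StructureError(f"{path}: {exc}") from exc
    sequences = [(rec.id, str(rec.seq).upper()) for rec in msa]
    ids = [i for i, (rid, _) in enumerate(sequences) if rid == query_id]
    if not ids:
        raise StructureError(f"{path}: query id {query_id!r} not present")
    return Alignment(sequences, ids[0])


# ---------------------------------------------------------------------------
# superposition


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired points P onto Q.

    Returns ``(R, t, rmsd)`` such that ``P @ R.T + t`` best fits ``Q`` in the
    least-squares sense, with ``det(R) = +1``.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise StructureError("paired coordinate sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise StructureError("need at least 3 paired atoms for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinear (rank < 2) point sets leave the rotation underdetermined
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise StructureError("degenerate (collinear) coordinates")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P0 @ R.T) - Q0
    rmsd = math.sqrt((diff ** 2).sum() / n)
    return R, t, rmsd


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    residue_selection: Sequence[tuple[tuple[int, int], tuple[int, int]]],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition over explicitly paired Calpha residue ranges.

    ``residue_selection`` is a list of ``((m_start, m_end), (r_start, r_end))``
    inclusive residue-number ranges; corresponding positions are paired in
    order. The pairing is explicit by design: no internal sequence alignment
    is attempted.
    """
    m_nums: list[int] = []
    r_nums: list[int] = []
    for (ms, me), (rs, re) in residue_selection:
        mm = list(range(ms, me + 1))
        rr = list(range(rs, re + 1))
        if len(mm) != len(rr):
            raise StructureError(
                f"range pair ({ms}-{me}, {rs}-{re}) has unequal lengths"
            )
        m_nums.extend(mm)
        r_nums.extend(rr)
    P = mobile.ca_coords(m_nums)
    Q = reference.ca_coords(r_nums)
    return kabsch(P, Q)


# ---------------------------------------------------------------------------
# trajectory frames


def read_frames(
    path_or_paths: str | Path | Sequence[str | Path],
    topology: StructureModel,
    stride: int = 1,
) -> FrameSeries:
    """Read trajectory frames matching ``topology``'s atom count.

    Multi-model PDB files are read natively; any other extension is handed
    to MDAnalysis (optional dependency) with the topology written to a
    temporary PDB.
    """
    if stride < 1:
        raise StructureError("stride must be >= 1")
    paths = (
        [Path(path_or_paths)]
        if isinstance(path_or_paths, (str, Path))
        else [Path(p) for p in path_or_paths]
    )
    n_atoms = sum(len(r.atoms) for r in topology.residues)
    frames: list[np.ndarray] = []
    for p in paths:
        if p.suffix.lower() in (".pdb", ".ent", ".cif"):
            frames.extend(_frames_from_pdb(p, n_atoms))
        else:
            frames.extend(_frames_via_mdanalysis(p, topology, n_atoms))
    if not frames:
        raise StructureError("no frames read")
    return FrameSeries(frames[::stride])


def _frames_from_pdb(path: Path, n_atoms: int) -> list[np.ndarray]:
    st = gemmi.read_structure(str(path))
    out = []
    for model in st:
        coords = [
            (at.pos.x, at.pos.y, at.pos.z)
            for ch in model
            for res in ch
            for at in res
        ]
        arr = np.array(coords, dtype=float)
        if arr.shape[0] != n_atoms:
            raise StructureError(
                f"{path}: frame has {arr.shape[0]} atoms, topology has {n_atoms}"
            )
        out.append(arr)
    return out


def _frames_via_mdanalysis(
    path: Path, topology: StructureModel, n_atoms: int
) -> list[np.ndarray]:
    import tempfile

    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise StructureError(
            f"{path}: reading {path.suffix} trajectories requires MDAnalysis"
        ) from exc
    with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as fh:
        write_structure(topology, fh.name)
        top_path = fh.name
    u = mda.Universe(top_path, str(path))
    if len(u.atoms) != n_atoms:
        raise StructureError(
            f"{path}: trajectory has {len(u.atoms)} atoms, topology has {n_atoms}"
        )
    return [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
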