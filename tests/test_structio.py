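"""Structure/alignment I/O round-trips and Kabsch superposition."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.optimize import minimize

import memstab
from memstab import fixtures as fx
from memstab.structio import StructureError, kabsch


def write_helix_pdb(tmp_path, bfactor, n=30):
    model = fx.make_helix_bundle(n_helices=1, residues_per_helix=n, seed=0,
                                 plddt_baseline=bfactor)
    path = tmp_path / "helix.pdb"
    memstab.write_structure(model, path)
    return model, path


class TestReadWrite:
    def test_plddt_identity_readback(self, tmp_path):
        _, path = write_helix_pdb(tmp_path, 95.0)
        model = memstab.read_structure(path)
        assert len(model) == 30
        assert np.allclose(model.plddt, 95.0)

    def test_fractional_scale_rescaled_to_percent(self, tmp_path):
        # AlphaFold files on the 0-1 dialect are multiplied by 100 on read
        _, path = write_helix_pdb(tmp_path, 0.95)
        model = memstab.read_structure(path)
        assert np.allclose(model.plddt, 95.0)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(Exception):
            memstab.read_structure(path)

    def test_coordinate_roundtrip_to_pdb_precision(self, tmp_path):
        original = fx.make_helix_bundle(seed=3)
        path = tmp_path / "bundle.pdb"
        memstab.write_structure(original, path)
        back = memstab.read_structure(path)
        assert back.sequence == original.sequence
        assert np.allclose(back.atom_coords(), original.atom_coords(), atol=1e-3)
        assert np.array_equal(back.plddt, original.plddt)

    def test_mixed_confidence_scales_rejected(self, tmp_path):
        model = fx.make_helix_bundle(n_helices=1, residues_per_helix=20, seed=0)
        plddt = np.full(20, 95.0)
        plddt[3] = 0.9  # fractional value inside a 0-100 file
        model.plddt = plddt
        path = tmp_path / "mixed.pdb"
        memstab.write_structure(model, path)
        with pytest.raises(StructureError, match="mixed"):
            memstab.read_structure(path)

    def test_missing_chain_rejected(self, tmp_path):
        _, path = write_helix_pdb(tmp_path, 95.0)
        with pytest.raises(StructureError, match="chain"):
            memstab.read_structure(path, chain="Z")


class TestAlignmentIO:
    def test_identical_rows_identity_column_map(self, tmp_path):
        aln = memstab.Alignment([("query", "ACDEFGHIKL")] * 1 +
                                [("h1", "ACDEFGHIKL"), ("h2", "ACDEFGHIKL")], 0)
        path = tmp_path / "aln.fasta"
        fx.write_alignment_fasta(aln, path)
        back = memstab.read_alignment(path, "query")
        assert back.column_map == {i: i for i in range(1, 11)}

    def test_gap_columns_skipped_in_column_map(self):
        aln = memstab.Alignment([("query", "AC-DE"), ("hit", "ACFDE")], 0)
        assert aln.column_map == {1: 1, 2: 2, 4: 3, 5: 4}

    def test_single_sequence_alignment_valid(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">query\nACDE\n")
        aln = memstab.read_alignment(path, "query")
        assert aln.n_rows == 1 and aln.query_sequence == "ACDE"

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "ragged.fasta"
        path.write_text(">query\nACDE\n>h1\nACD\n")
        with pytest.raises(StructureError):
            memstab.read_alignment(path, "query")

    def test_absent_query_rejected(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">a\nACDE\n>b\nACDE\n")
        with pytest.raises(StructureError, match="query"):
            memstab.read_alignment(path, "nope")


def brute_force_rmsd(P, Q, n_restarts=20):
    """Independent oracle: numerically minimize RMSD over rotation angles."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def cost(angles):
        R = Rotation.from_euler("xyz", angles).as_matrix()
        return np.sqrt((((P0 @ R.T) - Q0) ** 2).sum() / len(P0))

    best = np.inf
    rng = np.random.default_rng(0)
    for _ in range(n_restarts):
        x0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestSuperpose:
    def test_self_superposition_zero(self, bundle):
        _, _, rmsd = memstab.superpose(bundle, bundle, [((1, 210), (1, 210))])
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_invariance(self, bundle):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = bundle.with_coordinates(bundle.atom_coords() @ R.T + [5.0, 0.0, 0.0])
        _, _, rmsd = memstab.superpose(moved, bundle, [((1, 210), (1, 210))])
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_of_rmsd(self, bundle):
        rng = np.random.default_rng(4)
        noisy = bundle.with_coordinates(
            bundle.atom_coords() + rng.normal(0, 0.5, bundle.atom_coords().shape)
        )
        sel = [((1, 210), (1, 210))]
        _, _, ab = memstab.superpose(noisy, bundle, sel)
        _, _, ba = memstab.superpose(bundle, noisy, sel)
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_matches_brute_force_minimum(self):
        rng = np.random.default_rng(7)
        P = rng.normal(size=(5, 3))
        Q = P.copy()
        Q[2] += [1.0, 0.0, 0.0]  # one point displaced by 1 A
        _, _, rmsd = kabsch(P, Q)
        oracle = brute_force_rmsd(P, Q)
        assert rmsd == pytest.approx(oracle, abs=1e-4)

    def test_proper_rotation(self):
        rng = np.random.default_rng(8)
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        R, _, _ = kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(StructureError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(StructureError, match="collinear"):
            kabsch(P, P)


class TestFrames:
    def test_multimodel_pdb_roundtrip(self, tmp_path):
        model = fx.make_cavity_model("sphere", {"radius": 4.0})
        series = fx.make_frames(model, n_frames=3, motion="static")
        path = tmp_path / "frames.pdb"
        fx.write_frames_pdb(model, series, path)
        back = memstab.read_frames(path, model)
        assert len(back) == 3
        for f in back.frames:
            assert np.allclose(f, model.atom_coords(), atol=1e-3)

    def test_stride(self, tmp_path):
        model = fx.make_cavity_model("sphere", {"radius": 4.0})
        series = fx.make_frames(model, n_frames=10, motion="jitter", sigma=0.05, seed=0)
        path = tmp_path / "frames.pdb"
        fx.write_frames_pdb(model, series, path)
        back = memstab.read_frames(path, model, stride=2)
        assert len(back) == 5

    def test_atom_count_mismatch_rejected(self, tmp_path):
        model = fx.make_cavity_model("sphere", {"radius": 4.0})
        series = fx.make_frames(model, n_frames=2, motion="static")
        path = tmp_path / "frames.pdb"
        fx.write_frames_pdb(model, series, path)
        smaller = fx.make_cavity_model("sphere", {"radius": 3.0})
        with pytest.raises(StructureError, match="atoms"):
            memstab.read_frames(path, smaller)

    def test_nan_coordinates_rejected(self):
        bad = np.zeros((5, 3))
        bad[1, 2] = np.nan
        with pytest.raises(StructureError, match="NaN"):
            memstab.FrameSeries([bad])
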