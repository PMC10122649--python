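"""Grid pocket detection, funnel profiling and trajectory volume tracking."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import memstab
from memstab import fixtures as fx
from memstab.cavity import detect_pockets, funnel_profile, track_volumes


SPHERE_VOL = lambda r: 4.0 / 3.0 * np.pi * r ** 3


@pytest.fixture(scope="module")
def sphere6():
    return fx.make_cavity_model("sphere", {"radius": 6.0})


@pytest.fixture(scope="module")
def cone40():
    return fx.make_cavity_model(
        "cone", {"length": 40.0, "base_radius": 8.0, "tip_radius": 2.0}
    )


class TestDetectPockets:
    def test_hollow_sphere_analytic_volume(self, sphere6, slab_frame):
        ps = detect_pockets(sphere6, slab_frame, spacing=0.5)
        assert len(ps.pockets) == 1
        assert ps.pockets[0].volume == pytest.approx(SPHERE_VOL(6.0), rel=0.10)

    def test_single_atom_no_pockets(self, slab_frame):
        model = fx._points_to_model(np.array([[0.0, 0.0, 0.0]]))
        ps = detect_pockets(model, slab_frame, spacing=1.0)
        assert len(ps.pockets) == 0

    def test_two_disjoint_shells_additive_volumes(self, slab_frame):
        m1 = fx.make_cavity_model("sphere", {"radius": 5.0}, center=(0, 0, 0))
        m2 = fx.make_cavity_model("sphere", {"radius": 4.0}, center=(30, 0, 0))
        combined = fx._points_to_model(
            np.vstack([m1.atom_coords(), m2.atom_coords()])
        )
        ps = detect_pockets(combined, slab_frame, spacing=0.5)
        assert len(ps.pockets) == 2
        assert ps.pockets[0].volume == pytest.approx(SPHERE_VOL(5.0), rel=0.10)
        assert ps.pockets[1].volume == pytest.approx(SPHERE_VOL(4.0), rel=0.10)

    def test_volume_converges_with_grid_refinement(self, slab_frame):
        model = fx.make_cavity_model("sphere", {"radius": 5.0})
        v_coarse = detect_pockets(model, slab_frame, spacing=1.0).pockets[0].volume
        v_fine = detect_pockets(model, slab_frame, spacing=0.5).pockets[0].volume
        assert abs(v_fine - v_coarse) / v_fine < 0.05

    def test_rigid_transform_covariance(self, slab_frame):
        model = fx.make_cavity_model("sphere", {"radius": 5.0})
        ps0 = detect_pockets(model, slab_frame, spacing=0.5)
        R = Rotation.from_euler("xyz", [30, 45, 60], degrees=True).as_matrix()
        moved = model.with_coordinates(model.atom_coords() @ R.T + [7.0, -3.0, 2.0])
        ps1 = detect_pockets(moved, slab_frame, spacing=0.5)
        # one grid cell of slack either way
        assert abs(ps1.pockets[0].volume - ps0.pockets[0].volume) / ps0.pockets[0].volume < 0.05

    def test_empty_model_rejected(self, slab_frame):
        with pytest.raises(Exception):
            detect_pockets(
                memstab.StructureModel.__new__(memstab.StructureModel),
                slab_frame,
            )

    def test_min_cells_filters_small_clusters(self, slab_frame):
        model = fx.make_cavity_model("sphere", {"radius": 2.0})
        few = detect_pockets(model, slab_frame, spacing=1.0, min_cells=100)
        assert len(few.pockets) == 0

    def test_side_labels_match_construction(self):
        frame = memstab.MembraneFrame(np.zeros(3), np.array([0, 0, 1.0]), 15.0)
        model = fx.make_multi_cavity_model(
            [(4.5, (0, 0, 10)), (4.0, (11, 0, 0)), (2.5, (0, 0, -10))]
        )
        ps = detect_pockets(model, frame, spacing=1.0)
        assert len(ps.pockets) == 3
        labels = [p.side_label for p in ps.pockets]  # sorted by volume desc
        assert labels == ["cytoplasmic", "mid-membrane", "lumenal"]
        vols = [p.volume for p in ps.pockets]
        assert vols[0] > vols[1] > vols[2]


class TestFunnelProfile:
    def test_conical_cavity_length_and_flag(self, cone40, slab_frame):
        ps = detect_pockets(cone40, slab_frame, spacing=0.5)
        fp = funnel_profile(cone40, slab_frame, ps.pockets[0])
        assert fp.length == pytest.approx(40.0, abs=1.0)
        assert fp.is_funnel
        assert fp.spearman <= -0.5

    def test_cylindrical_cavity_not_a_funnel(self, slab_frame):
        cyl = fx.make_cavity_model("cylinder", {"length": 20.0, "radius": 4.0})
        ps = detect_pockets(cyl, slab_frame, spacing=0.5)
        fp = funnel_profile(cyl, slab_frame, ps.pockets[0])
        assert not fp.is_funnel

    def test_length_invariant_under_model_rotation(self, cone40):
        frame0 = memstab.MembraneFrame(np.zeros(3), np.array([0, 0, 1.0]), 15.0)
        ps0 = detect_pockets(cone40, frame0, spacing=0.5)
        fp0 = funnel_profile(cone40, frame0, ps0.pockets[0])
        R = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        rotated = cone40.with_coordinates(cone40.atom_coords() @ R.T)
        frame1 = memstab.MembraneFrame(np.zeros(3), R @ np.array([0, 0, 1.0]), 15.0)
        ps1 = detect_pockets(rotated, frame1, spacing=0.5)
        fp1 = funnel_profile(rotated, frame1, ps1.pockets[0])
        assert fp1.length == pytest.approx(fp0.length, abs=1.0)
        assert fp1.is_funnel

    def test_tiny_pocket_rejected(self, cone40, slab_frame):
        ps = detect_pockets(cone40, slab_frame, spacing=0.5)
        small = memstab.Pocket(
            cells=ps.pockets[0].cells[:3],
            volume=1.0,
            centroid=np.zeros(3),
            side_label="mid-membrane",
        )
        with pytest.raises(ValueError):
            funnel_profile(cone40, slab_frame, small)


class TestTrackVolumes:
    def test_static_frames_constant_volume(self, slab_frame):
        model = fx.make_cavity_model("sphere", {"radius": 5.0})
        frames = fx.make_frames(model, n_frames=5, motion="static")
        series = track_volumes(model, frames, slab_frame, spacing=1.0)
        assert series.volume_vs_time.shape == (5, 1)
        assert series.volume_vs_time[0].var() == 0.0

    def test_growing_shell_matches_analytic_means(self, slab_frame):
        model = fx.make_cavity_model("sphere", {"radius": 5.0})
        rate = 0.05
        frames = fx.make_frames(model, n_frames=4, motion="grow", growth_rate=rate)
        series = track_volumes(model, frames, slab_frame, spacing=0.5)
        shell_r = 5.0 + fx.SHELL_STANDOFF
        expected = np.mean(
            [SPHERE_VOL((1 + rate * k) * shell_r - fx.SHELL_STANDOFF) for k in range(4)]
        )
        assert series.mean_volumes[0] == pytest.approx(expected, rel=0.10)
        vols = series.volume_vs_time[0].to_numpy()
        assert (np.diff(vols) > 0).all()

    def test_jittered_frames_small_nonzero_variance(self, slab_frame):
        model = fx.make_cavity_model("sphere", {"radius": 5.0})
        frames = fx.make_frames(model, n_frames=6, motion="jitter", sigma=0.1, seed=2)
        series = track_volumes(model, frames, slab_frame, spacing=1.0)
        vols = series.volume_vs_time[0].to_numpy()
        assert np.isfinite(vols).all()
        assert 0 < np.std(vols) < 0.2 * np.mean(vols)

    def test_pocket_absent_in_frame_recorded_as_gap(self, slab_frame):
        m1 = fx.make_cavity_model("sphere", {"radius": 5.0})
        # second frame: shrink shell so the cavity falls below min_cells
        coords = m1.atom_coords()
        centroid = coords.mean(axis=0)
        shrunk = centroid + (coords - centroid) * 0.45
        frames = memstab.FrameSeries([coords, shrunk, coords.copy()])
        series = track_volumes(m1, frames, slab_frame, spacing=1.0, min_cells=10)
        col = series.volume_vs_time[0]
        assert np.isnan(col.iloc[1])
        assert col.iloc[0] > 0 and col.iloc[2] > 0
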