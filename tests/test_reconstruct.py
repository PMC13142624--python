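import numpy as np
import pytest

from tubetrace.phantom import PhantomSpec, make_tube_phantom
from tubetrace.reconstruct import (
    RegionAtlas,
    assign_regions,
    interpolate_cross_sections,
    load_straightened_hdf5,
    longitudinal_view,
    save_straightened_hdf5,
    straighten,
)
from tubetrace.segmentation import SegmentationModelSpec
from tubetrace.tracking import Track, TrackingConfig, track_tubule
from tubetrace.volume_io import OrientedPlane, sample_plane


@pytest.fixture(scope="module")
def arc_track():
    """90-degree arc tube (r=20 µm, bend radius 120 µm) and its track."""
    spec = PhantomSpec(
        centerline_model={
            "kind": "arc", "start": (60.0, 60.0, 60.0), "tangent": (0, 0, 1),
            "plane_normal": (-1, 0, 0), "radius": 120.0, "turn_deg": 90.0,
        },
        radius_profile={"kind": "constant", "radius": 20.0},
        volume_shape=(120, 280, 260),
        rng_seed=6,
    )
    grid, truth = make_tube_phantom(spec)
    tp = truth.centerline.points_um
    track = track_tubule(grid, (tp[0], tp[30]), TrackingConfig(), SegmentationModelSpec("d"),
                         stop_points=[tp[-1]], track_id="arc")
    assert track.status == "complete"
    return grid, truth, track


class TestVoxelReconstruction:
    def test_cylinder_volume_matches_analytic(self, straight_mm_phantom, straight_track):
        grid, truth, _, _ = straight_mm_phantom
        rec = interpolate_cross_sections(straight_track, grid)
        L = straight_track.length_um
        analytic = np.pi * 20.0**2 * L
        assert abs(rec.volume_um3 - analytic) / analytic < 0.10

    def test_truth_iou_of_reconstruction(self, straight_mm_phantom, straight_track):
        from tubetrace.morphometry import mask_metrics

        grid, truth, _, _ = straight_mm_phantom
        rec = interpolate_cross_sections(straight_track, grid)
        metrics = mask_metrics(rec.full(grid.shape), truth.mask)
        assert metrics["iou"] >= 0.85

    def test_node_centroids_are_foreground(self, straight_mm_phantom, straight_track):
        grid, _, _, _ = straight_mm_phantom
        rec = interpolate_cross_sections(straight_track, grid)
        for node in straight_track.nodes:
            if node.mask is not None:
                assert rec.contains_world(node.position_um)

    def test_single_node_rejected(self, straight_mm_phantom, straight_track):
        grid = straight_mm_phantom[0]
        stub = Track("stub", straight_track.seed1, straight_track.seed2,
                     [straight_track.nodes[0]])
        with pytest.raises(ValueError, match=">= 2 nodes"):
            interpolate_cross_sections(stub, grid)

    def test_foreground_confined_near_track(self, straight_mm_phantom, straight_track):
        grid, _, _, _ = straight_mm_phantom
        rec = interpolate_cross_sections(straight_track, grid)
        vox = np.argwhere(rec.crop) + rec.offset_vox
        world = vox * rec.spacing
        # lateral distance from the tube axis stays under D/2 + margin
        lateral = np.hypot(world[:, 0] - 35.0, world[:, 1] - 35.0)
        assert lateral.max() <= 85.0 / 2 + 5.0


class TestStraighten:
    def test_straight_tube_frames_equal_direct_slices(self, straight_mm_phantom):
        grid, truth, _, _ = straight_mm_phantom
        axis_track = Track.from_polyline(truth.centerline.points_um[::200], diameters=40.0)
        stack = straighten(grid, axis_track, 50.0, side_um=60.0)
        for i in (2, 5):
            direct = sample_plane(
                grid,
                OrientedPlane.from_normal(stack.planes[i].center, (0, 0, 1), 60.0, stack.pitch_um),
            ).raster
            assert np.allclose(stack.frames[i], direct, atol=1e-4)

    def test_frame_count_rule(self, straight_track, straight_mm_phantom):
        grid = straight_mm_phantom[0]
        stack = straighten(grid, straight_track, 100.0, side_um=60.0)
        assert len(stack.frames) == int(straight_track.length_um // 100.0) + 1

    def test_interval_equal_to_length_gives_two_frames(self, straight_track, straight_mm_phantom):
        grid = straight_mm_phantom[0]
        stack = straighten(grid, straight_track, straight_track.length_um, side_um=60.0)
        assert len(stack.frames) == 2

    def test_interval_longer_than_track_rejected(self, straight_track, straight_mm_phantom):
        grid = straight_mm_phantom[0]
        with pytest.raises(ValueError, match="interval"):
            straighten(grid, straight_track, straight_track.length_um + 1.0)

    def test_arc_tube_diameter_constant_when_straightened(self, arc_track):
        from tubetrace.segmentation import segment_plane, select_center_mask

        grid, truth, track = arc_track
        stack = straighten(grid, track, 20.0, side_um=100.0)
        model = SegmentationModelSpec("d", diameter_prior_um=40.0)
        diams = []
        for img in stack.plane_images()[1:-1]:
            mask = select_center_mask(segment_plane(img, model), img)
            if mask is not None:
                diams.append(mask.equiv_diameter_um)
        diams = np.array(diams)
        assert len(diams) >= 0.9 * (len(stack.frames) - 2)
        assert np.all(np.abs(diams - 40.0) / 40.0 < 0.10)

    def test_hdf5_round_trip(self, straight_track, straight_mm_phantom, tmp_path):
        grid = straight_mm_phantom[0]
        stack = straighten(grid, straight_track, 100.0, side_um=60.0)
        save_straightened_hdf5(stack, tmp_path / "s.h5")
        loaded = load_straightened_hdf5(tmp_path / "s.h5")
        assert np.allclose(loaded.frames, stack.frames)
        assert np.allclose(loaded.arc_um, stack.arc_um)


class TestLongitudinalView:
    def test_wall_bright_tube_shows_two_lines(self, straight_mm_phantom, straight_track):
        grid, _, _, _ = straight_mm_phantom
        stack = straighten(grid, straight_track, 25.0, side_um=60.0)
        view = longitudinal_view(stack)
        assert view.shape == (stack.frames.shape[1], len(stack.frames))
        profile = view[:, view.shape[1] // 2]
        bright = np.flatnonzero(profile > 60.0)
        # two wall bands roughly 2r = 40 µm apart
        assert bright.size > 0
        assert abs((bright.max() - bright.min()) - 40.0) < 6.0

    def test_single_frame_single_column(self, straight_mm_phantom, straight_track):
        grid = straight_mm_phantom[0]
        stack = straighten(grid, straight_track, straight_track.length_um, side_um=60.0)
        stack.frames = stack.frames[:1]
        view = longitudinal_view(stack)
        assert view.shape[1] == 1


class TestRegions:
    def test_planted_boundary_transition(self, straight_mm_phantom, straight_track):
        grid = straight_mm_phantom[0]
        labels = np.ones(grid.shape, np.uint8)
        labels[:, :, 530:] = 4  # boundary at z = 530 µm -> arc 500 from tube start
        atlas = RegionAtlas(labels, grid.spacing, {1: "cortex", 4: "IM"})
        node_labels, transitions = assign_regions(straight_track, atlas)
        assert set(node_labels) == {"cortex", "IM"}
        assert len(transitions) == 1
        assert abs(transitions[0] - 500.0) <= 9.0  # one node spacing

    def test_zero_atlas_all_unassigned(self, straight_mm_phantom, straight_track):
        grid = straight_mm_phantom[0]
        atlas = RegionAtlas(np.zeros(grid.shape, np.uint8), grid.spacing, {})
        node_labels, transitions = assign_regions(straight_track, atlas)
        assert set(node_labels) == {"unassigned"} and transitions == []

    def test_atlas_labels_must_be_mapped(self):
        with pytest.raises(ValueError, match="label map"):
            RegionAtlas(np.full((4, 4, 4), 7, np.uint8), (1, 1, 1), {1: "cortex"})
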