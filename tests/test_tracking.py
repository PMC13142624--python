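import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tubetrace.geometry import rotate_about_axis, unit
from tubetrace.morphometry import evaluate_tracking
from tubetrace.segmentation import SegmentationModelSpec, segment_plane, select_center_mask
from tubetrace.tracking import (
    Track,
    TrackingConfig,
    TubuleNetwork,
    apply_correction,
    consensus_from_hypotheses,
    find_branch_points,
    merge_tracks,
    resume_track,
    rotational_search,
    track_tubule,
    update_adaptive_params,
)
from tubetrace.volume_io import OrientedPlane, VoxelGrid, sample_plane

MODEL = SegmentationModelSpec("default")


class TestAdaptiveParams:
    def test_default_formulas_at_34(self):
        p = update_adaptive_params([34.0] * 5, TrackingConfig())
        assert (p.step_um, p.jitter_um, p.plane_side_um) == (7, 11, 85)
        assert p.d_prime_um == 34.0

    def test_clamping_to_physiological_bounds(self):
        p = update_adaptive_params([0.5], TrackingConfig())
        assert p.d_prime_um == 0.8
        p = update_adaptive_params([80.0], TrackingConfig())
        assert p.d_prime_um == 50.0

    def test_empty_history_uses_initial_diameter(self):
        p = update_adaptive_params([], TrackingConfig())
        assert p.d_prime_um == 34.0

    def test_running_average_uses_last_window(self):
        cfg = TrackingConfig(window=3)
        p = update_adaptive_params([10.0] * 10 + [40.0] * 3, cfg)
        assert p.d_prime_um == 40.0

    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_invariants_hold_for_any_history(self, diams):
        cfg = TrackingConfig()
        p = update_adaptive_params(diams, cfg)
        assert cfg.d_min_um <= p.d_prime_um <= cfg.d_max_um
        assert p.step_um == max(round(p.d_prime_um / cfg.k_step), 1)
        assert p.jitter_um == max(round(p.d_prime_um / cfg.k_jitter), 1)
        assert p.plane_side_um == max(round(p.d_prime_um * cfg.k_dim), 3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrackingConfig(d_min_um=10, d_init_um=5)
        with pytest.raises(ValueError):
            TrackingConfig(rotation_range_deg=60, rotation_step_deg=7)


class TestConsensus:
    def test_unanimous_hypotheses_returned_verbatim(self):
        disk = np.zeros((3, 5, 5), int)
        disk[:, 1:4, 1:4] = 1
        out = consensus_from_hypotheses([disk, disk, disk], 0)
        assert np.array_equal(out, disk[0] > 0)

    def test_majority_two_of_three(self):
        disk = np.zeros((3, 5, 5), int)
        disk[:, 1:4, 1:4] = 1
        out = consensus_from_hypotheses([disk, disk, np.zeros_like(disk)], 0)
        assert np.array_equal(out, disk[0] > 0)

    def test_depth_persistence_rule(self):
        thin = np.zeros((10, 5, 5), int)
        thin[:2, 1:4, 1:4] = 1  # present on 2 of 10 slices only
        assert consensus_from_hypotheses([thin, thin], 0) is None

    def test_center_background_returns_none(self):
        corner = np.zeros((3, 5, 5), int)
        corner[:, 0, 0] = 1
        assert consensus_from_hypotheses([corner, corner], 0) is None

    def test_all_empty_returns_none(self):
        z = np.zeros((3, 5, 5), int)
        assert consensus_from_hypotheses([z, z, z], 0) is None

    def test_mismatched_geometry_rejected(self):
        with pytest.raises(ValueError):
            consensus_from_hypotheses([np.zeros((3, 5, 5), int), np.zeros((3, 4, 4), int)], 0)


class TestRotationalSearch:
    def test_thirteen_candidates_with_defaults(self, straight_mm_phantom, monkeypatch):
        grid, truth, _, _ = straight_mm_phantom
        calls = []
        import tubetrace.tracking as tracking_mod

        real = tracking_mod.sample_plane
        monkeypatch.setattr(tracking_mod, "sample_plane", lambda v, p: calls.append(1) or real(v, p))
        plane, mask = _tilted_plane_mask(grid, tilt_deg=30.0)
        rotational_search(grid, plane, mask, MODEL, TrackingConfig(), 40.0)
        assert len(calls) == 13  # 120/10 + 1

    def test_recovers_tube_axis_from_pretilted_plane(self, straight_mm_phantom):
        grid, truth, _, _ = straight_mm_phantom
        plane, mask = _tilted_plane_mask(grid, tilt_deg=30.0)
        out = rotational_search(grid, plane, mask, MODEL, TrackingConfig(), 40.0)
        assert out is not None
        cand_plane, cand_mask, new_forward = out
        assert cand_mask.eccentricity < mask.eccentricity
        axis_angle = np.rad2deg(np.arccos(abs(np.dot(unit(new_forward), [0, 0, 1.0]))))
        assert axis_angle < 10.0

    def test_round_mask_does_not_trigger(self, straight_track):
        # on a straight tube the trigger never fires: no node carries the flag
        assert all("rotational_search_used" not in n.flags for n in straight_track.nodes)


def _tilted_plane_mask(grid, tilt_deg):
    n0 = rotate_about_axis(np.array([0.0, 0.0, 1.0]), (0, 1, 0), np.deg2rad(tilt_deg))
    plane = OrientedPlane.from_normal(np.array([35.0, 35.0, 500.0]), n0, 85.0, 1.0)
    img = sample_plane(grid, plane)
    mask = select_center_mask(segment_plane(img, MODEL, diameter_override_um=40.0), img)
    assert mask is not None
    return plane, mask


class TestTrackTubule:
    def test_straight_tube_completes_without_interventions(self, straight_track):
        track = straight_track
        assert track.status == "complete"
        assert track.flag is None
        # node count within 15% of L/S (L=1000, S=8 at d'=40)
        expected = 1000 / 8
        assert abs(len(track.nodes) - expected) / expected < 0.15

    def test_node_spacing_close_to_step(self, straight_track):
        spacing = np.diff(straight_track.arcs)
        assert np.all(spacing > 0)
        assert abs(np.median(spacing) - 8.0) <= 1.0

    def test_coincident_seeds_rejected(self, straight_mm_phantom):
        grid, _, seeds, _ = straight_mm_phantom
        with pytest.raises(ValueError, match="coincide"):
            track_tubule(grid, (seeds[0], seeds[0]), TrackingConfig(), MODEL)

    def test_seeds_outside_volume_rejected(self, straight_mm_phantom):
        grid, _, _, _ = straight_mm_phantom
        with pytest.raises(ValueError, match="inside"):
            track_tubule(grid, (np.array([-5.0, 0, 0]), np.array([0.0, 0, 10])), TrackingConfig(), MODEL)

    def test_tube_exiting_volume_terminates_at_boundary(self):
        # hand-built capless cylinder spanning the whole volume along z
        z, y, x = np.meshgrid(np.arange(60), np.arange(60), np.arange(260), indexing="ij")
        r = np.hypot(z - 30, y - 30)
        vol = np.where((r <= 20) & (r >= 14), 100.0, 20.0).astype(np.float32)
        vol += np.random.default_rng(0).normal(0, 3, vol.shape).astype(np.float32)
        grid = VoxelGrid(vol, spacing=(1, 1, 1))
        track = track_tubule(grid, (np.array([30.0, 30, 20]), np.array([30.0, 30, 27])), TrackingConfig(), MODEL)
        assert track.status == "terminated_boundary"
        assert track.points[-1][2] > 240  # reached the far face

    def test_identical_inputs_give_identical_tracks(self, straight_mm_phantom):
        grid, _, seeds, stop = straight_mm_phantom
        a = track_tubule(grid, seeds, TrackingConfig(), MODEL, stop_points=stop)
        b = track_tubule(grid, seeds, TrackingConfig(), MODEL, stop_points=stop)
        assert np.array_equal(a.points, b.points)
        assert [n.diameter_um for n in a.nodes] == [n.diameter_um for n in b.nodes]


class TestRecoveryModules:
    def test_step_phantom_recovered_by_troubleshooting(self, step_phantom, default_model):
        grid, truth, seeds, stop = step_phantom
        track = track_tubule(grid, seeds, TrackingConfig(), default_model, stop_points=stop)
        assert track.status == "complete"
        diams = [n.diameter_um for n in track.nodes]
        assert any(d < 20 for d in diams) and any(d > 35 for d in diams)
        assert any("troubleshoot_used" in n.flags for n in track.nodes)

    def test_step_phantom_flags_without_troubleshooting(self, step_phantom, default_model):
        grid, truth, seeds, stop = step_phantom
        track = track_tubule(grid, seeds, TrackingConfig(enable_ts=False), default_model, stop_points=stop)
        assert track.status == "flagged"
        assert track.flag is not None and track.flag.reason == "no_mask_any_model"

    def test_failure_always_produces_recovery_or_flag(self, step_phantom, default_model):
        # conservation: with TS off the failure surfaces as exactly one flag
        grid, truth, seeds, stop = step_phantom
        track = track_tubule(grid, seeds, TrackingConfig(enable_ts=False), default_model, stop_points=stop)
        assert (track.flag is not None) == (track.status == "flagged")

    def test_ablation_monotonicity_on_recovery_suite(self, kink_phantom, step_phantom, default_model):
        """Breaks with all modules enabled never exceed any single-module ablation."""
        def total_breaks(**toggles):
            breaks = 0
            for grid, truth in (kink_phantom, (step_phantom[0], step_phantom[1])):
                ev = evaluate_tracking(
                    grid, truth.centerline.points_um, truth.centerline.radii_um,
                    TrackingConfig(**toggles), [default_model],
                )
                breaks += ev.breaks
            return breaks

        full = total_breaks()
        assert full <= total_breaks(enable_rs=False)
        assert full <= total_breaks(enable_ts=False)
        assert full <= total_breaks(enable_ap=False)


class TestCorrections:
    def test_gap_flagged_then_resumed_to_completion(self, gap_phantom, default_model):
        grid, truth, seeds, stop = gap_phantom
        cfg = TrackingConfig()
        track = track_tubule(grid, seeds, cfg, default_model, stop_points=stop)
        assert track.status == "flagged"
        apply_correction(track, [np.array([35.0, 35.0, 390.0])], grid, resume=True)
        track = resume_track(grid, track, cfg, default_model, stop_points=stop)
        assert track.status == "complete"
        assert track.points[-1][2] > 500
        assert len(track.interventions) == 1

    def test_correction_on_unflagged_track_rejected(self, straight_track, straight_mm_phantom):
        grid = straight_mm_phantom[0]
        with pytest.raises(ValueError, match="flagged"):
            apply_correction(straight_track, [np.array([35.0, 35.0, 500.0])], grid)

    def test_correction_outside_volume_rejected(self, gap_phantom, default_model):
        grid, truth, seeds, stop = gap_phantom
        track = track_tubule(grid, seeds, TrackingConfig(), default_model, stop_points=stop)
        with pytest.raises(ValueError, match="outside"):
            apply_correction(track, [np.array([-10.0, 0.0, 0.0])], grid)


class TestNetwork:
    def test_y_phantom_single_branch_junction(self, y_phantom, default_model):
        grid, truth = y_phantom
        cfg = TrackingConfig()
        parent = track_tubule(grid, (np.array([60.0, 60, 40]), np.array([60.0, 60, 48])), cfg,
                              default_model, stop_points=[np.array([60.0, 60, 440])], track_id="parent")
        tip = truth.tubes[1].points_um[-1]
        back = tip - unit(truth.tubes[1].points_um[-1] - truth.tubes[1].points_um[-20]) * 6
        child = track_tubule(grid, (tip, back), cfg, default_model, existing_tracks=[parent], track_id="child")
        assert child.status == "terminated_merge"
        net = merge_tracks(TubuleNetwork(tracks=[parent, child]), 10.0)
        juncs = find_branch_points(net)
        branches = [j for j in juncs if j.kind == "branch"]
        assert len(branches) == 1 and branches[0].degree >= 3
        assert np.linalg.norm(branches[0].position_um - truth.junctions_um[0]) < 80.0

    def test_simple_chain_has_no_junctions(self, straight_track):
        net = merge_tracks(TubuleNetwork(tracks=[straight_track]), 10.0)
        assert find_branch_points(net) == []

    def test_duplicate_track_absorbed_into_single_centerline(self, straight_mm_phantom, straight_track, default_model):
        grid, truth, _, stop = straight_mm_phantom
        dup = track_tubule(grid, (np.array([35.0, 35, 500]), np.array([35.0, 35, 508])),
                           TrackingConfig(), default_model, stop_points=stop, track_id="dup")
        net = merge_tracks(TubuleNetwork(tracks=[straight_track, dup]), 10.0)
        assert [t.track_id for t in net.tracks] == [straight_track.track_id]
        assert net.tracks[0].length_um >= straight_track.length_um - 1

    def test_distant_tracks_unchanged(self):
        a = Track.from_polyline(np.stack([np.zeros(50), np.zeros(50), np.linspace(0, 500, 50)], 1), track_id="a")
        b = Track.from_polyline(np.stack([np.zeros(50), np.full(50, 400.0), np.linspace(0, 500, 50)], 1), track_id="b")
        net = merge_tracks(TubuleNetwork(tracks=[a, b]), 10.0)
        assert len(net.tracks) == 2 and not net.junctions

    def test_merge_is_idempotent(self, y_phantom, default_model):
        grid, truth = y_phantom
        parent = Track.from_polyline(truth.tubes[0].points_um[::40], diameters=40.0, track_id="p")
        child = Track.from_polyline(truth.tubes[1].points_um[::40], diameters=28.0, track_id="c")
        net1 = merge_tracks(TubuleNetwork(tracks=[parent, child]), 10.0)
        net2 = merge_tracks(TubuleNetwork(tracks=list(net1.tracks)), 10.0)
        assert len(net2.tracks) == len(net1.tracks)
        for t1, t2 in zip(sorted(net1.tracks, key=lambda t: t.track_id), sorted(net2.tracks, key=lambda t: t.track_id)):
            assert np.allclose(t1.points, t2.points)

    def test_reconnection_not_counted_as_extra_branch(self, reconnect_phantom, default_model):
        grid, truth = reconnect_phantom
        parent = track_tubule(grid, (np.array([60.0, 60, 40]), np.array([60.0, 60, 48])),
                              TrackingConfig(), default_model,
                              stop_points=[np.array([60.0, 60, 640])], track_id="parent")
        assert parent.status == "complete"
        child = Track.from_polyline(truth.tubes[1].points_um[::40], diameters=28.0, track_id="child")
        net = merge_tracks(TubuleNetwork(tracks=[parent, child]), 10.0)
        juncs = find_branch_points(net)
        assert sum(j.kind == "branch" for j in juncs) == 1
        assert sum(j.kind == "reconnection" for j in juncs) == 1
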