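import numpy as np
import pytest

from tubetrace.morphometry import (
    MorphometricProfile,
    NephronSummary,
    SegmentAnnotation,
    classify_loop_type,
    evaluate_tracking,
    mask_metrics,
    morphometric_profiles,
    segment_summary,
)
from tubetrace.segmentation import SegmentationModelSpec
from tubetrace.tracking import Track, TrackingConfig


def profile_of(points, step, diameters=20.0):
    return morphometric_profiles(Track.from_polyline(points, diameters), 0.0, step_um=step)


def line_pts(n=201, L=1000.0):
    t = np.linspace(0, L, n)
    return np.stack([np.zeros_like(t), np.zeros_like(t), t], 1)


def circle_pts(R=100.0, n=400):
    th = np.linspace(0, 1.8 * np.pi, n)
    return np.stack([np.zeros_like(th), R * np.sin(th), R * np.cos(th)], 1)


def helix_pts(R=50.0, c=25.0, n=1200):
    t = np.linspace(0, 6 * np.pi, n)
    return np.stack([c * t, R * np.sin(t), R * np.cos(t)], 1)


class TestProfiles:
    def test_line_has_zero_curvature_and_torsion(self):
        p = profile_of(line_pts(), 5.0)
        assert np.all(p.curvature_per_um == 0)
        assert np.all(p.torsion_per_um == 0)

    def test_circle_curvature_is_inverse_radius(self):
        p = profile_of(circle_pts(R=100.0), 5.0)
        inner = slice(5, -5)
        assert np.allclose(p.curvature_per_um[inner], 0.01, rtol=0.05)
        assert np.all(np.abs(p.torsion_per_um[inner]) < 1e-4)

    def test_helix_curvature_and_torsion(self):
        p = profile_of(helix_pts(R=50.0, c=25.0), 5.0)
        inner = slice(5, -5)
        assert np.allclose(p.curvature_per_um[inner], 50 / 3125, rtol=0.05)
        assert np.allclose(np.abs(p.torsion_per_um[inner]), 25 / 3125, rtol=0.05)

    def test_estimates_converge_with_step(self):
        errs_k, errs_t = [], []
        for step in (40.0, 20.0, 10.0):
            p = profile_of(helix_pts(), step)
            inner = slice(3, -3)
            errs_k.append(abs(p.curvature_per_um[inner].mean() - 50 / 3125))
            errs_t.append(abs(np.abs(p.torsion_per_um[inner]).mean() - 25 / 3125))
        assert errs_k[0] >= errs_k[1] >= errs_k[2]
        assert errs_t[0] >= errs_t[1] >= errs_t[2]

    def test_profiles_invariant_to_rigid_rotation(self):
        from tubetrace.geometry import rotate_about_axis

        pts = helix_pts()
        rot = np.stack([rotate_about_axis(p, (0, 1, 0), 0.7) for p in pts])
        p1 = profile_of(pts, 10.0)
        p2 = profile_of(rot, 10.0)
        inner = slice(5, -5)
        assert np.allclose(p1.curvature_per_um[inner], p2.curvature_per_um[inner], rtol=0.01, atol=1e-6)
        assert np.allclose(p1.torsion_per_um[inner], p2.torsion_per_um[inner], rtol=0.01, atol=1e-6)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="4 nodes"):
            profile_of(line_pts(n=3), 5.0)

    def test_grid_strictly_increasing_and_curvature_nonnegative(self):
        p = profile_of(helix_pts(), 7.0)
        assert np.all(np.diff(p.arc_um) > 0)
        assert np.all(p.curvature_per_um >= 0)


class TestLoopClassification:
    def test_short_thin_limb_is_sln(self):
        s = NephronSummary({"thin_limb": 800.0})
        assert classify_loop_type(s)[0] == "SLN"

    def test_long_thin_limb_is_lln(self):
        s = NephronSummary({"thin_limb": 2000.0})
        assert classify_loop_type(s)[0] == "LLN"

    def test_inner_medulla_entry_is_lln(self):
        s = NephronSummary({}, region_labels=["cortex", "OSOM", "IM"])
        cls, rule = classify_loop_type(s)
        assert cls == "LLN" and rule == "inner_medulla_entry"

    def test_no_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_loop_type(NephronSummary({}))


class TestSegmentSummary:
    @staticmethod
    def _planted_profile():
        arc = np.arange(0.0, 3000.0, 10.0)
        diam = np.where(arc < 1000, 40.0, np.where(arc < 2000, 16.0, 24.0))
        rng = np.random.default_rng(0)
        diam = diam + rng.normal(0, 0.5, diam.shape)
        return MorphometricProfile(arc, diam, np.zeros_like(arc), np.zeros_like(arc))

    def test_planted_segment_diameters_recovered(self):
        prof = self._planted_profile()
        ann = SegmentAnnotation([(0.0, 1000.0, "PCT"), (1000.0, 2000.0, "thin_limb"), (2000.0, 3000.0, "thick_limb")])
        out = segment_summary(prof, ann).set_index("segment")
        for seg, d in (("PCT", 40.0), ("thin_limb", 16.0), ("thick_limb", 24.0)):
            assert abs(out.loc[seg, "diameter_mean_um"] - d) / d < 0.05

    def test_single_segment_equals_whole_profile(self):
        prof = self._planted_profile()
        out = segment_summary(prof, SegmentAnnotation([(0.0, 3000.0, "all")]))
        assert np.isclose(out.iloc[0]["diameter_mean_um"], prof.diameter_um.mean())

    def test_empty_interval_list_gives_empty_summary(self):
        prof = self._planted_profile()
        assert segment_summary(prof, SegmentAnnotation([])).empty

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SegmentAnnotation([(0.0, 100.0, "a"), (50.0, 150.0, "b")])


class TestEvaluateTracking:
    def test_flawless_run_zero_breaks(self, straight_mm_phantom):
        grid, truth, _, _ = straight_mm_phantom
        ev = evaluate_tracking(grid, truth.centerline.points_um, truth.centerline.radii_um,
                               TrackingConfig(), [SegmentationModelSpec("d")])
        assert ev.breaks == 0
        assert len(ev.uninterrupted_lengths_um) == 1
        assert abs(ev.uninterrupted_lengths_um[0] - truth.centerline.length_um) < 50.0

    def test_gap_without_troubleshooting_breaks(self, gap_phantom):
        grid, truth, _, _ = gap_phantom
        ev = evaluate_tracking(grid, truth.centerline.points_um, truth.centerline.radii_um,
                               TrackingConfig(enable_ts=False), [SegmentationModelSpec("d")])
        assert ev.breaks >= 1

    def test_uninterrupted_lengths_conserved(self, gap_phantom):
        grid, truth, _, _ = gap_phantom
        ev = evaluate_tracking(grid, truth.centerline.points_um, truth.centerline.radii_um,
                               TrackingConfig(enable_ts=False), [SegmentationModelSpec("d")])
        assert sum(ev.uninterrupted_lengths_um) <= truth.centerline.length_um + 50.0

    def test_empty_truth_rejected(self, straight_mm_phantom):
        grid = straight_mm_phantom[0]
        with pytest.raises(ValueError, match="truth"):
            evaluate_tracking(grid, np.zeros((1, 3)), np.array([20.0]), TrackingConfig(), [SegmentationModelSpec("d")])


class TestMaskMetrics:
    def test_identical_masks_all_ones(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        out = mask_metrics(m, m)
        assert all(np.isclose(v, 1.0) for v in out.values())

    def test_disjoint_masks_zero(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = True
        b[4, 4, 4] = True
        out = mask_metrics(a, b)
        assert out["iou"] == 0.0 and out["f1"] == 0.0

    def test_half_overlap_closed_form(self):
        a = np.zeros(8, bool)
        b = np.zeros(8, bool)
        a[:4] = True
        b[2:6] = True
        out = mask_metrics(a, b)
        assert np.isclose(out["iou"], 1 / 3)
        assert np.isclose(out["f1"], 1 / 2)
        assert np.isclose(out["f1"], 2 * out["precision"] * out["recall"] / (out["precision"] + out["recall"]))

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mask_metrics(np.zeros(4, bool), np.zeros(4, bool))
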