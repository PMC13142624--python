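"""Stepwise vector tracking of tubule centerlines with automated recovery.

The tracker follows a tubule from a seed-point pair: at each step the forward
direction is estimated from the two most recent centerline nodes, a plane
orthogonal to it is sampled at an adaptive step ahead, segmented, and the node
is repositioned to the centroid of the mask overlapping the plane center.

Three recovery modules keep the loop alive across diameter changes, bends and
staining failures, each invoked only when needed:

* **Adaptive parameters (AP)** — step size S, plane side D and diameter
  jitter J are derived from a running average d' of recent cross-section
  diameters: S = round(d'/k_step), J = round(d'/k_jitter), D = round(d'*k_dim),
  with d' clamped to physiological bounds.
* **Rotational search (RS)** — when a cross-section is highly elongated, the
  plane is rotated about the ellipse's minor axis r = -sin(phi) u + cos(phi) v
  over a sweep of candidate angles; the roundest candidate wins, and its
  normal becomes the new forward direction.
* **Troubleshooting / model switching (TS)** — when no center mask is found,
  a local slab (10 slices deep, target plane first) is segmented under a
  diameter sweep {d', d'-J, d'+J}; the hypotheses are fused by majority vote
  with a depth-persistence rule (stage 1); failing that, the sweep is repeated
  across the whole model suite and the model whose hypothesis best matches the
  consensus (highest IoU) is adopted for subsequent steps (stage 2).

Tracks that exhaust all recovery end in a flag-queue entry for manual
correction; a correction appends one or more manual nodes, after which
tracking resumes.  Finished tracks are merged into a network by centerline
distance, and junctions where three or more segments meet are classified as
branch points (or reconnections where a descendant segment rejoins its own
tubule's path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .geometry import resample_polyline, rotate_about_axis, transport_frame, unit
from .segmentation import (
    CrossSectionMask,
    SegmentationModelSpec,
    mask_statistics,
    segment_plane,
    select_center_mask,
)
from .volume_io import (
    OrientedPlane,
    PlaneImage,
    VoxelGrid,
    default_pitch,
    extract_local_slab,
    sample_plane,
)

__all__ = [
    "TrackingConfig",
    "RuntimeParams",
    "CenterlineNode",
    "Track",
    "TubuleNetwork",
    "FlagQueueEntry",
    "Junction",
    "update_adaptive_params",
    "rotational_search",
    "consensus_from_hypotheses",
    "troubleshoot",
    "track_tubule",
    "resume_track",
    "apply_correction",
    "merge_tracks",
    "find_branch_points",
    "Tracker",
]


@dataclass
class TrackingConfig:
    """Tunable tracking parameters (distances in µm, angles in degrees)."""

    k_step: float = 5.0
    k_jitter: float = 3.0
    k_dim: float = 2.5
    window: int = 10  # W: running-average window, in nodes
    d_min_um: float = 0.8
    d_max_um: float = 50.0
    d_init_um: float = 34.0
    rotation_range_deg: float = 60.0
    rotation_step_deg: float = 10.0
    eccentricity_trigger: float = 0.75  # ~1.5:1 elongation; see docs/methods.md
    ts_depth: int = 10
    diameter_band: float = 2.0  # accepted mask d within [d'/band, band*d']
    max_steps: int = 5000
    merge_tolerance_um: float = 10.0
    stall_backtrack_frac: float = 0.25  # stall if node within frac*S of an old node
    stall_reversal_dot: float = -0.5
    enable_ap: bool = True
    enable_rs: bool = True
    enable_ts: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.d_min_um <= self.d_init_um <= self.d_max_um):
            raise ValueError("require 0 < d_min <= d_init <= d_max")
        n = self.rotation_range_deg / self.rotation_step_deg
        if abs(n - round(n)) > 1e-9:
            raise ValueError("rotation_step must divide rotation_range evenly")


@dataclass
class RuntimeParams:
    """Per-step derived parameters."""

    step_um: float  # S
    jitter_um: float  # J
    plane_side_um: float  # D
    d_prime_um: float


@dataclass
class CenterlineNode:
    position_um: np.ndarray
    s_um: float
    diameter_um: float
    mask: CrossSectionMask | None
    model_id: str
    flags: set = field(default_factory=set)


@dataclass
class FlagQueueEntry:
    track_id: str
    node_index: int
    reason: str  # no_mask_any_model | stall | boundary | manual_stop
    params: RuntimeParams | None = None


@dataclass
class Track:
    track_id: str
    seed1: np.ndarray
    seed2: np.ndarray
    nodes: list[CenterlineNode] = field(default_factory=list)
    status: str = "active"  # active|flagged|complete|terminated_boundary|terminated_merge
    interventions: list[dict] = field(default_factory=list)
    flag: FlagQueueEntry | None = None
    model_index: int = 0

    @property
    def points(self) -> np.ndarray:
        return np.array([n.position_um for n in self.nodes])

    @property
    def arcs(self) -> np.ndarray:
        return np.array([n.s_um for n in self.nodes])

    @property
    def length_um(self) -> float:
        return float(self.nodes[-1].s_um) if self.nodes else 0.0

    @classmethod
    def from_polyline(
        cls,
        points: np.ndarray,
        diameters: np.ndarray | float = 20.0,
        track_id: str = "poly",
    ) -> "Track":
        """Build a mask-less track from an (N, 3) polyline (analysis helper)."""
        points = np.asarray(points, float)
        diam = np.broadcast_to(np.asarray(diameters, float), (len(points),))
        arcs = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
        nodes = [
            CenterlineNode(points[i].copy(), float(arcs[i]), float(diam[i]), None, "truth")
            for i in range(len(points))
        ]
        return cls(track_id, points[0].copy(), points[min(1, len(points) - 1)].copy(), nodes, "complete")


@dataclass
class Junction:
    position_um: np.ndarray
    host_track: str
    guest_track: str
    guest_end: str  # "head" | "tail"
    host_interior: bool
    kind: str = ""  # filled by find_branch_points: branch | reconnection | merge
    degree: int = 0


@dataclass
class TubuleNetwork:
    tracks: list[Track] = field(default_factory=list)
    junctions: list[Junction] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Adaptive parameters
# ---------------------------------------------------------------------------


def update_adaptive_params(
    recent_diameters_um: list[float] | np.ndarray, config: TrackingConfig
) -> RuntimeParams:
    """Derive S, J, D from the clamped running-average diameter d'.

    d' is the mean of up to W most recent cross-section diameters (the
    configured initial diameter when no history exists), clamped to
    [d_min, d_max]; then S = round(d'/k_step), J = round(d'/k_jitter),
    D = round(d'*k_dim), all in µm.
    """
    hist = np.asarray(recent_diameters_um, dtype=float)
    if hist.size == 0:
        d_prime = config.d_init_um
    else:
        d_prime = float(np.mean(hist[-config.window :]))
    d_prime = float(np.clip(d_prime, config.d_min_um, config.d_max_um))
    s = max(round(d_prime / config.k_step), 1.0)
    j = max(round(d_prime / config.k_jitter), 1.0)
    d_side = max(round(d_prime * config.k_dim), 3.0)
    return RuntimeParams(step_um=s, jitter_um=j, plane_side_um=d_side, d_prime_um=d_prime)


def _in_band(diameter_um: float, prior_um: float, band: float) -> bool:
    return prior_um / band <= diameter_um <= prior_um * band


# ---------------------------------------------------------------------------
# Rotational search
# ---------------------------------------------------------------------------


def rotational_search(
    volume: VoxelGrid,
    plane: OrientedPlane,
    mask: CrossSectionMask,
    model: SegmentationModelSpec,
    config: TrackingConfig,
    d_prime_um: float,
) -> tuple[OrientedPlane, CrossSectionMask, np.ndarray] | None:
    """Sweep candidate planes about the ellipse minor axis; keep the roundest.

    Returns (plane, mask, new forward direction) or None when every candidate
    fails to segment.  Ties in eccentricity break toward the smallest |angle|.
    """
    phi = mask.phi_rad
    r_axis = unit(-np.sin(phi) * plane.u + np.cos(phi) * plane.v)
    n_steps = int(round(config.rotation_range_deg / config.rotation_step_deg))
    angles = [config.rotation_step_deg * k for k in range(-n_steps, n_steps + 1)]
    angles.sort(key=abs)  # evaluation order implements the tie-break
    best: tuple[float, OrientedPlane, CrossSectionMask] | None = None
    for ang in angles:
        rad = np.deg2rad(ang)
        n2 = unit(rotate_about_axis(plane.normal, r_axis, rad))
        u2 = unit(rotate_about_axis(plane.u, r_axis, rad))
        v2 = np.cross(n2, u2)
        cand = OrientedPlane(plane.center, n2, u2, v2, plane.side_um, plane.pitch_um)
        img = sample_plane(volume, cand)
        outcome = segment_plane(img, model, diameter_override_um=d_prime_um)
        m = select_center_mask(outcome, img)
        if m is None:
            continue
        if best is None or m.eccentricity < best[0] - 1e-12:
            best = (m.eccentricity, cand, m)
    if best is None:
        return None
    _, cand, m = best
    return cand, m, cand.normal


# ---------------------------------------------------------------------------
# Troubleshooting and model switching
# ---------------------------------------------------------------------------


def consensus_from_hypotheses(
    hypothesis_label_slabs: list[np.ndarray], target_plane_index: int = 0
) -> np.ndarray | None:
    """Fuse hypothesis slabs by per-pixel majority vote with depth persistence.

    Hypotheses whose slab contains no foreground anywhere abstain from the
    vote; a pixel is consensus foreground iff at least half of the voting
    hypotheses mark it.  The consensus is restricted to the 26-connected 3D
    component containing the target-plane center, which must span at least
    half the slab depth.  Returns that component's target-plane cross-section,
    or None.
    """
    if len(hypothesis_label_slabs) < 2:
        raise ValueError("need >= 2 hypotheses")
    shapes = {s.shape for s in hypothesis_label_slabs}
    if len(shapes) != 1:
        raise ValueError("hypothesis slabs must share geometry")
    fg = [np.asarray(s) > 0 for s in hypothesis_label_slabs]
    voters = [f for f in fg if f.any()]
    if not voters:
        return None
    votes = np.sum(voters, axis=0)
    consensus = votes * 2 >= len(voters)
    labels, _ = ndi.label(consensus, structure=np.ones((3, 3, 3), dtype=int))
    depth, h, w = consensus.shape
    lab = labels[target_plane_index, h // 2, w // 2]
    if lab == 0:
        return None
    comp = labels == lab
    span = int(np.count_nonzero(comp.any(axis=(1, 2))))
    if 2 * span < depth:
        return None
    return comp[target_plane_index]


def _hypothesis_slab(
    slab_images: list[PlaneImage],
    model: SegmentationModelSpec,
    prior_um: float,
    band: float,
) -> np.ndarray:
    """Segment each slab slice under a diameter prior; keep in-band objects."""
    out = np.zeros((len(slab_images),) + slab_images[0].raster.shape, dtype=np.int32)
    for j, img in enumerate(slab_images):
        outcome = segment_plane(img, model, diameter_override_um=prior_um)
        labels = outcome.labels
        if not outcome.success:
            continue
        n = labels.max()
        areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        d_eq = 2.0 * np.sqrt(areas * img.pixel_pitch_um**2 / np.pi)
        keep = np.flatnonzero(
            (d_eq >= prior_um / band) & (d_eq <= prior_um * band)
        ) + 1
        out[j] = np.where(np.isin(labels, keep), labels, 0)
    return out


def _center_mask_of_slab(slab: np.ndarray, image: PlaneImage) -> np.ndarray | None:
    labels2d, _ = ndi.label(slab[0] > 0)
    h, w = labels2d.shape
    lab = labels2d[h // 2, w // 2]
    if lab == 0:
        return None
    return labels2d == lab


def _iou(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    return (inter / union if union else 0.0), union


def troubleshoot(
    volume: VoxelGrid,
    plane: OrientedPlane,
    params: RuntimeParams,
    config: TrackingConfig,
    models: list[SegmentationModelSpec],
    incumbent_index: int,
) -> tuple[CrossSectionMask, int, float] | None:
    """Two-stage recovery when standard segmentation finds no center mask.

    Stage 1 sweeps the incumbent model over diameters {d', d'-J, d'+J} on a
    local slab and fuses the hypotheses by consensus.  Stage 2 repeats the
    sweep across the whole model suite.  Returns (mask, adopted model index,
    adopted diameter) where the adopted diameter/model come from the
    hypothesis with the highest IoU against the consensus (ties break toward
    the incumbent model, then toward the larger IoU union).
    """
    d_prime, jit = params.d_prime_um, params.jitter_um
    priors = []
    for p in (d_prime, d_prime - jit, d_prime + jit):
        p = float(np.clip(p, config.d_min_um, config.d_max_um))
        if p not in priors:
            priors.append(p)
    slab_images = extract_local_slab(volume, plane, config.ts_depth)
    target_img = slab_images[0]

    def run_stage(model_indices: list[int]) -> tuple[CrossSectionMask, int, float] | None:
        hyps: list[tuple[int, float, np.ndarray]] = []
        for mi in model_indices:
            for prior in priors:
                hyps.append(
                    (mi, prior, _hypothesis_slab(slab_images, models[mi], prior, config.diameter_band))
                )
        slabs = [h[2] for h in hyps]
        if len(slabs) < 2:
            slabs = slabs + [np.zeros_like(slabs[0])]
        consensus = consensus_from_hypotheses(slabs, target_plane_index=0)
        if consensus is None or not consensus.any():
            return None
        best: tuple[float, int, int, float, np.ndarray] | None = None
        for mi, prior, slab in hyps:
            cm = _center_mask_of_slab(slab, target_img)
            if cm is None:
                continue
            iou, union = _iou(cm, consensus)
            incumbent_bonus = 1 if mi == incumbent_index else 0
            key = (iou, incumbent_bonus, union)
            if best is None or key > (best[0], best[1], best[2]):
                best = (iou, incumbent_bonus, union, prior, cm)
        mask = mask_statistics(consensus, target_img, models[incumbent_index].model_id)
        if best is None:
            return mask, incumbent_index, mask.equiv_diameter_um
        # recover which model the best hypothesis used
        for mi, prior, slab in hyps:
            cm = _center_mask_of_slab(slab, target_img)
            if cm is None:
                continue
            iou, union = _iou(cm, consensus)
            if (iou, 1 if mi == incumbent_index else 0, union) == (best[0], best[1], best[2]):
                d_adopt = float(2.0 * np.sqrt(np.count_nonzero(cm) * target_img.pixel_pitch_um**2 / np.pi))
                return mask, mi, d_adopt
        return mask, incumbent_index, mask.equiv_diameter_um

    result = run_stage([incumbent_index])
    if result is not None:
        return result
    if len(models) > 1:
        return run_stage(list(range(len(models))))
    return None


# ---------------------------------------------------------------------------
# The tracker
# ---------------------------------------------------------------------------


class Tracker:
    """Stateful stepwise vector tracker for one tubule."""

    def __init__(
        self,
        volume: VoxelGrid,
        config: TrackingConfig,
        models: list[SegmentationModelSpec],
        existing_tracks: list[Track] | None = None,
        stop_points: list[np.ndarray] | None = None,
    ):
        if not models:
            raise ValueError("at least one segmentation model is required")
        self.volume = volume
        self.config = config
        self.models = models
        self.pitch = default_pitch(volume)
        self.stop_points = [np.asarray(p, float) for p in (stop_points or [])]
        pts = [t.points for t in (existing_tracks or []) if len(t.nodes) >= 2]
        self._existing_tree = cKDTree(np.concatenate(pts)) if pts else None

    # -- single step -------------------------------------------------------

    def _acquire_mask(
        self, plane: OrientedPlane, params: RuntimeParams, track: Track
    ) -> tuple[CrossSectionMask | None, np.ndarray | None, set]:
        """Segment a plane with the recovery cascade.

        Returns (mask, forward override from RS, node flags).  A None mask
        means every enabled recovery stage failed.
        """
        cfg = self.config
        flags: set = set()
        img = sample_plane(self.volume, plane)
        model = self.models[track.model_index]
        outcome = segment_plane(img, model, diameter_override_um=params.d_prime_um)
        mask = select_center_mask(outcome, img)
        forward_override = None
        if (
            mask is not None
            and mask.eccentricity >= cfg.eccentricity_trigger
            and cfg.enable_rs
        ):
            rs = rotational_search(self.volume, plane, mask, model, cfg, params.d_prime_um)
            flags.add("rotational_search_used")
            if rs is not None:
                plane, mask, forward_override = rs
        if mask is not None and not _in_band(
            mask.equiv_diameter_um, params.d_prime_um, cfg.diameter_band
        ):
            mask = None  # scale-inconsistent mask: treat as segmentation failure
        if mask is None and cfg.enable_ts:
            ts = troubleshoot(self.volume, plane, params, cfg, self.models, track.model_index)
            flags.add("troubleshoot_used")
            if ts is not None:
                mask, model_index, d_adopt = ts
                track.model_index = model_index
                mask.equiv_diameter_um = d_adopt if d_adopt > 0 else mask.equiv_diameter_um
        return mask, forward_override, flags

    def step(self, track: Track, forward: np.ndarray, frame_uv) -> tuple[np.ndarray, tuple] | None:
        """Advance the track by one node; returns (forward, frame) or None on stop."""
        cfg = self.config
        params = self._params(track)
        last = track.nodes[-1]
        proposed = last.position_um + params.step_um * forward
        if not self.volume.contains_world(proposed):
            track.status = "terminated_boundary"
            return None
        for sp in self.stop_points:
            if np.linalg.norm(proposed - sp) <= cfg.merge_tolerance_um:
                track.status = "complete"
                return None
        if self._existing_tree is not None:
            # cross-sections fuse once centerlines are about one diameter
            # apart (sum of the two radii), so stop there, not at contact
            d, _ = self._existing_tree.query(proposed)
            if d <= max(cfg.merge_tolerance_um, 1.25 * params.d_prime_um):
                track.status = "terminated_merge"
                return None
        u, v = frame_uv
        plane = OrientedPlane(proposed, forward, u, v, params.plane_side_um, self.pitch)
        mask, forward_override, flags = self._acquire_mask(plane, params, track)
        if mask is None:
            track.status = "flagged"
            track.flag = FlagQueueEntry(track.track_id, len(track.nodes), "no_mask_any_model", params)
            return None
        new_pos = mask.centroid_um
        step_len = float(np.linalg.norm(new_pos - last.position_um))
        if step_len < 1e-9:
            new_pos = proposed
            step_len = params.step_um
        new_forward = (
            unit(forward_override) if forward_override is not None else unit(new_pos - last.position_um)
        )
        # stall detection: backtracking onto an old node, or direction reversal
        if np.dot(new_forward, forward) < cfg.stall_reversal_dot:
            track.status = "flagged"
            track.flag = FlagQueueEntry(track.track_id, len(track.nodes), "stall", params)
            return None
        old = track.points[:-3]
        if len(old) and np.min(np.linalg.norm(old - new_pos, axis=1)) < cfg.stall_backtrack_frac * params.step_um:
            track.status = "flagged"
            track.flag = FlagQueueEntry(track.track_id, len(track.nodes), "stall", params)
            return None
        node = CenterlineNode(
            position_um=new_pos,
            s_um=last.s_um + step_len,
            diameter_um=mask.equiv_diameter_um,
            mask=mask,
            model_id=self.models[track.model_index].model_id,
            flags=flags,
        )
        track.nodes.append(node)
        u2, v2 = transport_frame(u, v, plane.normal, new_forward)
        return new_forward, (u2, v2)

    def _params(self, track: Track) -> RuntimeParams:
        if not self.config.enable_ap:
            return update_adaptive_params([], self.config)
        diams = [n.diameter_um for n in track.nodes if n.diameter_um > 0]
        return update_adaptive_params(diams, self.config)

    # -- full run ----------------------------------------------------------

    def run(self, seed1: np.ndarray, seed2: np.ndarray, track_id: str = "t0") -> Track:
        seed1 = np.asarray(seed1, float)
        seed2 = np.asarray(seed2, float)
        if not (self.volume.contains_world(seed1) and self.volume.contains_world(seed2)):
            raise ValueError("seed points must lie inside the volume")
        if np.linalg.norm(seed2 - seed1) < 1e-9:
            raise ValueError("seed points must not coincide")
        track = Track(track_id, seed1, seed2)
        forward = unit(seed2 - seed1)
        params = update_adaptive_params([], self.config)
        plane = OrientedPlane.from_normal(seed1, forward, params.plane_side_um, self.pitch)
        mask, _, flags = self._acquire_mask(plane, params, track)
        if mask is None:
            track.status = "flagged"
            track.flag = FlagQueueEntry(track_id, 0, "no_mask_any_model", params)
            return track
        track.nodes.append(
            CenterlineNode(mask.centroid_um, 0.0, mask.equiv_diameter_um, mask,
                           self.models[track.model_index].model_id, flags)
        )
        frame = (plane.u, plane.v)
        return self._loop(track, forward, frame)

    def _loop(self, track: Track, forward: np.ndarray, frame) -> Track:
        track.status = "active"
        while len(track.nodes) < self.config.max_steps and track.status == "active":
            out = self.step(track, forward, frame)
            if out is None:
                break
            forward, frame = out
        if track.status == "active":
            track.status = "complete"
        return track

    def resume(self, track: Track) -> Track:
        """Continue a corrected track from its last two nodes."""
        if len(track.nodes) < 2:
            raise ValueError("resume requires at least two nodes")
        p1, p0 = track.nodes[-2].position_um, track.nodes[-1].position_um
        forward = unit(p0 - p1)
        from .geometry import orthonormal_basis

        _, u, v = orthonormal_basis(forward)
        return self._loop(track, forward, (u, v))


def track_tubule(
    volume: VoxelGrid,
    seeds: tuple[np.ndarray, np.ndarray],
    config: TrackingConfig,
    models: list[SegmentationModelSpec] | SegmentationModelSpec,
    existing_tracks: list[Track] | None = None,
    stop_points: list[np.ndarray] | None = None,
    track_id: str = "t0",
) -> Track:
    """Track one tubule from a seed pair; see :class:`Tracker`."""
    if isinstance(models, SegmentationModelSpec):
        models = [models]
    tracker = Tracker(volume, config, models, existing_tracks, stop_points)
    return tracker.run(seeds[0], seeds[1], track_id)


def resume_track(
    volume: VoxelGrid,
    track: Track,
    config: TrackingConfig,
    models: list[SegmentationModelSpec] | SegmentationModelSpec,
    existing_tracks: list[Track] | None = None,
    stop_points: list[np.ndarray] | None = None,
) -> Track:
    if isinstance(models, SegmentationModelSpec):
        models = [models]
    tracker = Tracker(volume, config, models, existing_tracks, stop_points)
    return tracker.resume(track)


def apply_correction(
    track: Track,
    points_um: np.ndarray | list,
    volume: VoxelGrid,
    resume: bool = True,
) -> Track:
    """Append manual node(s) to a flagged track and clear its flag.

    The forward direction is recomputed from the last two nodes; if ``resume``
    the track status returns to active so tracking can continue.
    """
    if track.status != "flagged" or track.flag is None:
        raise ValueError("corrections apply only to flagged tracks")
    pts = np.atleast_2d(np.asarray(points_um, float))
    for p in pts:
        if not volume.contains_world(p):
            raise ValueError(f"correction point {p} lies outside the volume")
        last = track.nodes[-1]
        step = float(np.linalg.norm(p - last.position_um))
        track.nodes.append(
            CenterlineNode(p.copy(), last.s_um + step, last.diameter_um, None,
                           last.model_id, {"manual_correction"})
        )
    track.interventions.append(
        {"type": "correction", "points": pts.tolist(), "at_node": track.flag.node_index}
    )
    track.flag = None
    track.status = "active" if resume else "complete"
    return track


# ---------------------------------------------------------------------------
# Track merging and branch points
# ---------------------------------------------------------------------------


def merge_tracks(network: TubuleNetwork, tolerance_um: float) -> TubuleNetwork:
    """Merge overlapping centerlines; truncate the shorter overlapping portion.

    Tracks are visited longest-first.  Where a track's nodes run within
    ``tolerance_um`` of an already-kept centerline, the overlapping head/tail
    run is cut away and replaced by a junction at the attachment point; tracks
    overlapping everywhere are absorbed.  Idempotent on a merged network.
    """
    step = tolerance_um / 2.0
    ordered = sorted(network.tracks, key=lambda t: -t.length_um)
    kept: list[Track] = []
    kept_pts: list[np.ndarray] = []
    kept_ids: list[str] = []
    kept_arcs: list[np.ndarray] = []
    junctions: list[Junction] = []
    for tr in ordered:
        if len(tr.nodes) < 2:
            kept.append(tr)
            continue
        if not kept_pts:
            kept.append(tr)
            pts, arcs = resample_polyline(tr.points, step)
            kept_pts.append(pts)
            kept_ids.append(tr.track_id)
            kept_arcs.append(arcs)
            continue
        concat = np.concatenate(kept_pts)
        owner = np.concatenate([np.full(len(p), i) for i, p in enumerate(kept_pts)])
        arc_of = np.concatenate(kept_arcs)
        tree = cKDTree(concat)
        node_pts = tr.points
        d, idx = tree.query(node_pts)
        overlap = d <= tolerance_um
        if overlap.all():
            continue  # duplicate reconstruction of an already-kept tubule
        first_free = int(np.argmax(~overlap))
        last_free = len(overlap) - 1 - int(np.argmax(~overlap[::-1]))
        new_nodes = tr.nodes[first_free : last_free + 1]
        if first_free > 0:
            j = idx[first_free - 1]
            host = kept[owner[j]]
            junctions.append(
                Junction(concat[j].copy(), host.track_id, tr.track_id, "head",
                         _interior(arc_of[j], kept_arcs[owner[j]][-1], tolerance_um))
            )
        if last_free < len(overlap) - 1:
            j = idx[last_free + 1]
            host = kept[owner[j]]
            junctions.append(
                Junction(concat[j].copy(), host.track_id, tr.track_id, "tail",
                         _interior(arc_of[j], kept_arcs[owner[j]][-1], tolerance_um))
            )
        trimmed = Track(
            tr.track_id, tr.seed1, tr.seed2, list(new_nodes), tr.status,
            tr.interventions, tr.flag, tr.model_index,
        )
        # endpoint attachment: a track terminating where its wall meets
        # another centerline forms a junction even without node overlap
        for end, node in (("head", trimmed.nodes[0]), ("tail", trimmed.nodes[-1])):
            if any(j.guest_track == trimmed.track_id and j.guest_end == end for j in junctions):
                continue
            attach_tol = tolerance_um + node.diameter_um
            d_end, j_end = tree.query(node.position_um)
            if d_end <= attach_tol:
                host = kept[owner[j_end]]
                junctions.append(
                    Junction(
                        concat[j_end].copy(), host.track_id, trimmed.track_id, end,
                        _interior(arc_of[j_end], kept_arcs[owner[j_end]][-1], tolerance_um),
                    )
                )
        kept.append(trimmed)
        pts, arcs = resample_polyline(trimmed.points, step)
        kept_pts.append(pts)
        kept_ids.append(trimmed.track_id)
        kept_arcs.append(arcs)
    return TubuleNetwork(tracks=kept, junctions=junctions)


def _interior(arc: float, total: float, tol: float) -> bool:
    return tol < arc < total - tol


def find_branch_points(network: TubuleNetwork) -> list[Junction]:
    """Classify junctions of a merged network as branch or reconnection points.

    A junction where >= 3 segments meet is a branch point; when a guest
    segment attaches to the same host at both its head and tail (it rejoins
    its own tubule's path), the downstream attachment is a reconnection and
    is not counted as an additional branch.
    """
    juncs = network.junctions
    # group guest attachments
    by_guest: dict[str, list[Junction]] = {}
    for j in juncs:
        by_guest.setdefault(j.guest_track, []).append(j)
    for j in juncs:
        j.degree = (2 if j.host_interior else 1) + 1
        siblings = by_guest[j.guest_track]
        rejoins = (
            len(siblings) >= 2
            and len({s.host_track for s in siblings}) == 1
            and {s.guest_end for s in siblings} >= {"head", "tail"}
        )
        if rejoins and j.guest_end == "tail":
            j.kind = "reconnection"
        elif j.degree >= 3:
            j.kind = "branch"
        else:
            j.kind = "merge"
    return list(juncs)
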