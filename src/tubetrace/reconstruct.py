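"""Voxel reconstruction, straightening, and region annotation of tracks.

Cross-section masks along a track are encoded as radial contour functions
r(theta) about their centroids (64 spokes), linearly interpolated between
consecutive nodes at sub-voxel arc steps, and stamped as filled polygons into
the source volume's voxel grid at native resolution.  The radial encoding
assumes approximately star-convex cross-sections, which holds for tubule
lumina; strongly non-convex masks fall back to the nearest node's contour.

Straightened stacks resample orthogonal planes at uniform arc length with
rotation-minimizing frames, turning a coiled tubule into a flat image stack
for longitudinal cut-through views and per-plane corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as draw_polygon

from .geometry import orthonormal_basis, resample_polyline, transport_frame
from .tracking import Track
from .volume_io import OrientedPlane, PlaneImage, VoxelGrid, default_pitch, sample_plane

__all__ = [
    "TubuleVolumeMask",
    "StraightenedStack",
    "RegionAtlas",
    "interpolate_cross_sections",
    "straighten",
    "longitudinal_view",
    "assign_regions",
    "save_straightened_hdf5",
    "load_straightened_hdf5",
]

N_SPOKES = 64


@dataclass
class TubuleVolumeMask:
    """Binary reconstruction stored as a bounding-box crop + voxel offset."""

    crop: np.ndarray  # bool
    offset_vox: np.ndarray  # (z, y, x) index of crop[0,0,0] in the source grid
    spacing: np.ndarray
    track_id: str

    def full(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        z, y, x = self.offset_vox
        out[z : z + self.crop.shape[0], y : y + self.crop.shape[1], x : x + self.crop.shape[2]] = self.crop
        return out

    def contains_world(self, world_um: np.ndarray) -> bool:
        idx = np.round(np.asarray(world_um, float) / self.spacing).astype(int) - self.offset_vox
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.crop.shape)):
            return False
        return bool(self.crop[tuple(idx)])

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_um3(self) -> float:
        return float(np.count_nonzero(self.crop)) * self.voxel_volume_um3


@dataclass
class StraightenedStack:
    """Square cross-sections resampled at uniform arc-length intervals."""

    frames: np.ndarray  # (n_frames, side, side)
    interval_um: float
    arc_um: np.ndarray  # per-frame arc length
    pitch_um: float
    planes: list[OrientedPlane]
    track_id: str = ""

    def plane_images(self) -> list[PlaneImage]:
        return [
            PlaneImage(self.frames[i], self.planes[i], np.zeros_like(self.frames[i], bool))
            for i in range(len(self.frames))
        ]


@dataclass
class RegionAtlas:
    """Label raster aligned to a volume, e.g. 1=cortex 2=OSOM 3=ISOM 4=IM."""

    labels: np.ndarray
    spacing: np.ndarray
    label_map: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, float)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"atlas labels {sorted(missing)} missing from the label map")

    def label_at(self, world_um: np.ndarray) -> str:
        idx = np.round(np.asarray(world_um, float) / self.spacing).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.labels.shape) - 1)
        val = int(self.labels[tuple(idx)])
        return self.label_map.get(val, "unassigned") if val != 0 else "unassigned"


# ---------------------------------------------------------------------------
# Radial contour encoding
# ---------------------------------------------------------------------------


def _radial_contour(mask: np.ndarray, centroid_px: np.ndarray, pitch: float) -> np.ndarray:
    """r(theta) in µm about the centroid, sampled at N_SPOKES angles.

    Walks each spoke outward at half-pixel steps and records the last radius
    still inside the mask (star-convex reading of the contour).
    """
    h, w = mask.shape
    thetas = 2 * np.pi * np.arange(N_SPOKES) / N_SPOKES
    max_r = float(np.hypot(h, w))  # px
    steps = np.arange(0.0, max_r, 0.5)
    rr = centroid_px[0] + np.outer(steps, np.cos(thetas))
    cc = centroid_px[1] + np.outer(steps, np.sin(thetas))
    inside = (
        (rr >= 0) & (rr <= h - 1) & (cc >= 0) & (cc <= w - 1)
    )
    ri = np.clip(np.round(rr).astype(int), 0, h - 1)
    ci = np.clip(np.round(cc).astype(int), 0, w - 1)
    hit = mask[ri, ci] & inside
    # last contiguous inside run from the centroid outwards
    radii = np.zeros(N_SPOKES)
    for k in range(N_SPOKES):
        run = hit[:, k]
        off = np.flatnonzero(~run)
        end = off[0] if off.size else len(run)
        radii[k] = steps[max(end - 1, 0)]
    return radii * pitch


def rebuild_masks(track: Track, volume: VoxelGrid, model=None) -> Track:
    """Re-segment cross-sections for a track whose masks were not persisted.

    Serialized tracks keep node positions and diameters but drop the mask
    rasters; this re-samples a plane at each node (normal from the adjacent
    nodes, side 2.5x the node diameter) and re-segments it with the node's
    diameter as the prior, attaching the center mask where one is found.
    """
    from .geometry import unit
    from .segmentation import SegmentationModelSpec, segment_plane, select_center_mask

    if model is None:
        model = SegmentationModelSpec("rebuild")
    pitch = default_pitch(volume)
    pts = track.points
    for i, node in enumerate(track.nodes):
        if node.mask is not None:
            continue
        a = pts[max(i - 1, 0)]
        b = pts[min(i + 1, len(pts) - 1)]
        if np.linalg.norm(b - a) < 1e-9:
            continue
        plane = OrientedPlane.from_normal(node.position_um, unit(b - a),
                                          max(2.5 * node.diameter_um, 6 * pitch), pitch)
        img = sample_plane(volume, plane)
        node.mask = select_center_mask(
            segment_plane(img, model, diameter_override_um=node.diameter_um), img
        )
    return track


def interpolate_cross_sections(track: Track, volume: VoxelGrid) -> TubuleVolumeMask:
    """Voxelize a track by interpolating its cross-section contours in 3D."""
    nodes = [n for n in track.nodes if n.mask is not None]
    if len(nodes) < 2:
        raise ValueError("reconstruction requires >= 2 nodes with masks")
    spacing = volume.spacing
    min_sp = float(min(spacing))
    pitch = default_pitch(volume)

    centers = np.array([n.position_um for n in nodes])
    arcs = np.array([n.s_um for n in nodes])
    contours = np.array(
        [_radial_contour(n.mask.mask, n.mask.centroid_px, n.mask.plane_image.pixel_pitch_um) for n in nodes]
    )
    normals = np.array([n.mask.plane_image.plane.normal for n in nodes])

    # bounding box: node centers dilated by max radius + margin
    r_max = float(contours.max())
    lo = np.maximum(np.floor((centers.min(axis=0) - r_max - 2 * min_sp) / spacing), 0).astype(int)
    hi = np.minimum(
        np.ceil((centers.max(axis=0) + r_max + 2 * min_sp) / spacing), np.asarray(volume.shape) - 1
    ).astype(int)
    crop = np.zeros(hi - lo + 1, dtype=bool)

    thetas = 2 * np.pi * np.arange(N_SPOKES) / N_SPOKES
    step = min_sp / 2.0
    # transported frame for stable spoke angles along the tube
    _, u, v = orthonormal_basis(normals[0])
    n_prev = normals[0]
    for i in range(len(nodes) - 1):
        seg = float(arcs[i + 1] - arcs[i])
        n_sub = max(int(np.ceil(seg / step)), 1)
        u, v = transport_frame(u, v, n_prev, normals[i])
        n_prev = normals[i]
        for j in range(n_sub + (1 if i == len(nodes) - 2 else 0)):
            w = j / n_sub
            c = (1 - w) * centers[i] + w * centers[i + 1]
            radii = (1 - w) * contours[i] + w * contours[i + 1]
            ring = c + np.outer(radii * np.cos(thetas), u) + np.outer(radii * np.sin(thetas), v)
            _stamp_polygon(crop, ring, c, u, v, radii, lo, spacing, pitch)
    return TubuleVolumeMask(crop=crop, offset_vox=lo, spacing=spacing, track_id=track.track_id)


def _stamp_polygon(crop, ring, center, u, v, radii, lo, spacing, pitch) -> None:
    """Fill one cross-section polygon into the crop at native resolution."""
    r_max = float(radii.max())
    if r_max <= 0:
        return
    half = int(np.ceil(r_max / pitch)) + 1
    # polygon vertices in local plane pixel coordinates
    pr = radii * np.cos(2 * np.pi * np.arange(N_SPOKES) / N_SPOKES) / pitch + half
    pc = radii * np.sin(2 * np.pi * np.arange(N_SPOKES) / N_SPOKES) / pitch + half
    rr, cc = draw_polygon(pr, pc, shape=(2 * half + 1, 2 * half + 1))
    if rr.size == 0:
        return
    world = center + ((rr - half) * pitch)[:, None] * u + ((cc - half) * pitch)[:, None] * v
    idx = np.round(world / spacing).astype(int) - lo
    ok = np.all((idx >= 0) & (idx < np.asarray(crop.shape)), axis=1)
    idx = idx[ok]
    crop[idx[:, 0], idx[:, 1], idx[:, 2]] = True


# ---------------------------------------------------------------------------
# Straightening
# ---------------------------------------------------------------------------


def straighten(
    volume: VoxelGrid,
    track: Track,
    interval_um: float,
    side_um: float | None = None,
    pitch_um: float | None = None,
) -> StraightenedStack:
    """Resample orthogonal planes at uniform arc length along the centerline.

    Frame count = floor(track length / interval) + 1; in-plane axes are
    propagated by rotation-minimizing transport so the stack does not spin.
    """
    if interval_um <= 0:
        raise ValueError("interval must be positive")
    pts = track.points
    length = track.length_um
    if interval_um > length:
        raise ValueError("interval exceeds track length")
    pitch = pitch_um if pitch_um is not None else default_pitch(volume)
    if side_um is None:
        dmax = max((n.diameter_um for n in track.nodes), default=34.0)
        side_um = 2.5 * dmax
    n_frames = int(np.floor(length / interval_um)) + 1
    grid = np.minimum(np.arange(n_frames) * interval_um, length)
    resampled, arcs = resample_polyline(pts, max(interval_um / 4.0, 1e-3))
    centers = np.empty((n_frames, 3))
    for k in range(3):
        centers[:, k] = np.interp(grid, arcs, resampled[:, k])
    tangents = np.gradient(resampled, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    frames = []
    planes = []
    t_prev = tangents[0]
    _, u, v = orthonormal_basis(t_prev)
    for i in range(n_frames):
        ti = tangents[min(int(np.searchsorted(arcs, grid[i])), len(tangents) - 1)]
        u, v = transport_frame(u, v, t_prev, ti)
        t_prev = ti
        plane = OrientedPlane(centers[i], ti, u, v, side_um, pitch)
        img = sample_plane(volume, plane)
        frames.append(img.raster)
        planes.append(plane)
    return StraightenedStack(
        frames=np.stack(frames),
        interval_um=interval_um,
        arc_um=grid,
        pitch_um=pitch,
        planes=planes,
        track_id=track.track_id,
    )


def longitudinal_view(stack: StraightenedStack, mode: str = "central") -> np.ndarray:
    """2D cut-through: column j is the central row (or max projection) of frame j."""
    if len(stack.frames) == 0:
        raise ValueError("empty stack")
    if mode == "central":
        cols = stack.frames[:, stack.frames.shape[1] // 2, :]
    elif mode == "max":
        cols = stack.frames.max(axis=1)
    else:
        raise ValueError("mode must be 'central' or 'max'")
    return cols.T  # (frame side, frame count)


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------


def assign_regions(track: Track, atlas: RegionAtlas) -> tuple[list[str], list[float]]:
    """Per-node atlas labels and the arc lengths where the label changes."""
    labels = [atlas.label_at(n.position_um) for n in track.nodes]
    transitions = [
        float(track.nodes[i].s_um)
        for i in range(1, len(labels))
        if labels[i] != labels[i - 1]
    ]
    return labels, transitions


# ---------------------------------------------------------------------------
# HDF5 round trip for straightened stacks
# ---------------------------------------------------------------------------


def save_straightened_hdf5(stack: StraightenedStack, path) -> None:
    import h5py

    with h5py.File(str(path), "w") as f:
        ds = f.create_dataset("frames", data=stack.frames.astype(np.float32))
        ds.attrs["interval_um"] = stack.interval_um
        ds.attrs["pitch_um"] = stack.pitch_um
        ds.attrs["track_id"] = stack.track_id
        f.create_dataset("arc_um", data=stack.arc_um)
        f.create_dataset("plane_centers", data=np.array([p.center for p in stack.planes]))
        f.create_dataset("plane_normals", data=np.array([p.normal for p in stack.planes]))
        f.create_dataset("plane_u", data=np.array([p.u for p in stack.planes]))
        f.create_dataset("plane_v", data=np.array([p.v for p in stack.planes]))


def load_straightened_hdf5(path) -> StraightenedStack:
    import h5py

    with h5py.File(str(path), "r") as f:
        frames = f["frames"][:]
        interval = float(f["frames"].attrs["interval_um"])
        pitch = float(f["frames"].attrs["pitch_um"])
        tid = str(f["frames"].attrs["track_id"])
        arc = f["arc_um"][:]
        centers = f["plane_centers"][:]
        normals = f["plane_normals"][:]
        us = f["plane_u"][:]
        vs = f["plane_v"][:]
    side = frames.shape[1] * pitch
    planes = [
        OrientedPlane(centers[i], normals[i], us[i], vs[i], side, pitch)
        for i in range(len(frames))
    ]
    return StraightenedStack(frames, interval, arc, pitch, planes, tid)
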