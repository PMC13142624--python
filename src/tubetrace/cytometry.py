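"""Nucleus detection, assignment to tubule reconstructions, and densities.

Nuclei from a DNA channel are assigned to a tubule when their centroid voxel
is foreground in that tubule's voxel reconstruction; densities per unit
length and per unit reconstruction volume are computed over consecutive
20 µm windows along the centerline, with segment-level values reported as
the mean across a segment's windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .reconstruct import TubuleVolumeMask
from .tracking import Track
from .volume_io import VoxelGrid

__all__ = [
    "NucleusRecord",
    "DensityProfile",
    "detect_nuclei",
    "assign_nuclei",
    "density_profiles",
]

DEFAULT_WINDOW_UM = 20.0


@dataclass
class NucleusRecord:
    centroid_um: np.ndarray
    volume_um3: float | None = None
    track_id: str | None = None


@dataclass
class DensityProfile:
    window_start_um: np.ndarray
    window_um: float
    counts: np.ndarray
    linear_density_per_um: np.ndarray
    volumetric_density_per_um3: np.ndarray  # NaN where window volume is zero
    segment_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start_um": self.window_start_um,
                "count": self.counts,
                "linear_density_per_um": self.linear_density_per_um,
                "volumetric_density_per_um3": self.volumetric_density_per_um3,
            }
        )


def detect_nuclei(
    volume: VoxelGrid,
    bbox_vox: tuple[np.ndarray, np.ndarray] | None = None,
    backend: str = "builtin-blob",
    min_radius_um: float = 2.0,
) -> list[NucleusRecord]:
    """Detect blob-like nuclei in (a crop of) the nuclei channel.

    The built-in backend smooths, thresholds (Otsu), splits touching blobs by
    watershed on the distance transform, and reports one centroid per object.
    """
    if backend != "builtin-blob":
        raise RuntimeError(f"nucleus detection backend {backend!r} is not available")
    if bbox_vox is not None:
        lo, hi = (np.asarray(b, int) for b in bbox_vox)
        crop = volume.intensities[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        offset = lo
    else:
        crop = volume.intensities
        offset = np.zeros(3, int)
    if crop.size == 0:
        return []
    img = ndi.gaussian_filter(crop.astype(np.float32), sigma=min_radius_um / (2 * volume.spacing))
    if img.max() - img.min() < 1e-9:
        return []
    bw = img > threshold_otsu(img)
    if not bw.any():
        return []
    dist = ndi.distance_transform_edt(bw, sampling=volume.spacing)
    min_sep_vox = np.maximum((min_radius_um / volume.spacing).astype(int), 1)
    peaks = peak_local_max(
        dist, min_distance=int(min_sep_vox.max()), labels=bw, exclude_border=False
    )
    if len(peaks) == 0:
        labels, n = ndi.label(bw)
    else:
        markers = np.zeros_like(bw, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers, mask=bw)
        n = labels.max()
    voxel_vol = float(np.prod(volume.spacing))
    records = []
    min_vox = max(int((4.0 / 3.0) * np.pi * min_radius_um**3 / voxel_vol * 0.2), 2)
    for lab in range(1, n + 1):
        sel = labels == lab
        cnt = int(np.count_nonzero(sel))
        if cnt < min_vox:
            continue
        com = ndi.center_of_mass(sel)
        world = (np.asarray(com) + offset) * volume.spacing + volume.origin
        records.append(NucleusRecord(world, volume_um3=cnt * voxel_vol))
    return records


def assign_nuclei(
    nuclei: list[NucleusRecord], reconstruction: TubuleVolumeMask
) -> list[NucleusRecord]:
    """Assign each nucleus whose centroid voxel is reconstruction foreground."""
    for rec in nuclei:
        if rec.track_id is None and reconstruction.contains_world(rec.centroid_um):
            rec.track_id = reconstruction.track_id
    return nuclei


def density_profiles(
    assigned: list[NucleusRecord],
    track: Track,
    reconstruction: TubuleVolumeMask,
    window_um: float = DEFAULT_WINDOW_UM,
    annotation=None,
) -> DensityProfile:
    """Nuclei densities in consecutive windows along the centerline.

    Each assigned nucleus maps to the arc length of its nearest centerline
    point (ties resolve to the earlier window); volumetric density divides the
    window count by the reconstruction volume whose voxels are nearest to that
    window (NaN when that volume is zero).
    """
    if window_um <= 0:
        raise ValueError("window must be positive")
    pts = track.points
    arcs = track.arcs
    total = float(arcs[-1])
    n_win = max(int(np.ceil(total / window_um)), 1)
    starts = np.arange(n_win) * window_um
    counts = np.zeros(n_win, dtype=int)
    tree = cKDTree(pts)
    mine = [r for r in assigned if r.track_id == track.track_id]
    for rec in mine:
        _, i = tree.query(rec.centroid_um)
        w = min(int(arcs[i] // window_um), n_win - 1)
        counts[w] += 1
    # window volume: reconstruction voxels binned by nearest centerline arc
    vox = np.argwhere(reconstruction.crop)
    vol_per_window = np.zeros(n_win)
    if len(vox):
        world = (vox + reconstruction.offset_vox) * reconstruction.spacing
        _, vi = tree.query(world)
        wbin = np.minimum((arcs[vi] // window_um).astype(int), n_win - 1)
        np.add.at(vol_per_window, wbin, reconstruction.voxel_volume_um3)
    linear = counts / window_um
    with np.errstate(divide="ignore", invalid="ignore"):
        volumetric = np.where(vol_per_window > 0, counts / vol_per_window, np.nan)
    profile = DensityProfile(starts, window_um, counts, linear, volumetric)
    if annotation is not None:
        for s0, s1, label in annotation.intervals:
            sel = (starts >= s0) & (starts + window_um <= s1)
            if not np.any(sel):
                continue
            profile.segment_means[label] = {
                "linear_density_per_um": float(np.mean(linear[sel])),
                "volumetric_density_per_um3": float(np.nanmean(volumetric[sel])),
                "count": float(np.sum(counts[sel])),
            }
    return profile
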