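"""2D cross-section segmentation with pluggable backends and mask geometry.

Two classical built-in backends keep the pipeline testable without trained
weights: ``builtin-threshold`` (Otsu threshold, hole filling, small-object
removal) and ``builtin-lumen`` (the same on the inverted image, for stains
where the structure of interest is dim).  A registry hook accepts drop-in
learned segmenters with the contract (raster, diameter prior in px) ->
labeled raster.

Mask geometry (area, equivalent circular diameter d = 2*sqrt(A/pi), the
second-moment ellipse with in-plane orientation phi and eccentricity
e = sqrt(1 - (minor/major)^2)) drives the tracker's adaptive parameters and
rotational search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity
from skimage.transform import downscale_local_mean

from .volume_io import PlaneImage

__all__ = [
    "SegmentationModelSpec",
    "SegmentationOutcome",
    "CrossSectionMask",
    "FrameSelectionParams",
    "segment_plane",
    "select_center_mask",
    "fit_ellipse",
    "select_training_frames",
    "register_backend",
]


@dataclass
class SegmentationModelSpec:
    """A segmentation model: backend + expected object scale (µm)."""

    model_id: str
    backend_key: str = "builtin-threshold"
    diameter_prior_um: float = 34.0
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diameter_prior_um <= 0:
            raise ValueError("diameter prior must be positive")


@dataclass
class SegmentationOutcome:
    labels: np.ndarray  # 0 = background, k >= 1 = object k (contiguous)
    model_id: str
    success: bool


@dataclass
class CrossSectionMask:
    """Selected binary cross-section with ellipse and diameter statistics."""

    mask: np.ndarray
    plane_image: PlaneImage
    centroid_px: np.ndarray  # (row, col)
    centroid_um: np.ndarray  # world (z, y, x)
    area_um2: float
    equiv_diameter_um: float
    major_um: float
    minor_um: float
    phi_rad: float
    eccentricity: float


@dataclass
class FrameSelectionParams:
    """Greedy SSIM-based diversity selection thresholds."""

    alpha: float  # local change vs the previously kept frame
    beta: float  # global change vs all kept frames (mean)
    t: float  # minimum interval along the centerline (in frame-spacing units)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must be in [0, 1]")
        if self.t < 0:
            raise ValueError("t must be >= 0")


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

BackendFn = Callable[..., np.ndarray]
_BACKENDS: dict[str, BackendFn] = {}


def register_backend(key: str, fn: BackendFn) -> None:
    """Register a plugin backend: (raster, diameter_prior_px, valid=...) -> labels.

    ``valid`` is a boolean mask of in-bounds pixels; out-of-bounds pixels are
    zero-filled by plane sampling and must not influence the segmentation.
    """
    _BACKENDS[key] = fn


def _threshold_backend(
    raster: np.ndarray, prior_px: float, invert: bool = False, valid: np.ndarray | None = None
) -> np.ndarray:
    img = raster.astype(np.float32)
    if valid is None:
        valid = np.ones(img.shape, dtype=bool)
    if not valid.any():
        return np.zeros(img.shape, dtype=np.int32)
    vals = img[valid]
    if invert:
        img = vals.max() - img
        vals = img[valid]
    if vals.max() - vals.min() < 1e-9:
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(vals)
    bw = (img > thr) & valid
    bw = ndi.binary_fill_holes(bw)
    min_area_px = (0.25 * prior_px) ** 2
    labels, n = ndi.label(bw)
    if n:
        areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= min_area_px) + 1
        bw = np.isin(labels, keep)
    labels, _ = ndi.label(bw)
    return labels.astype(np.int32)


register_backend(
    "builtin-threshold", lambda r, p, valid=None: _threshold_backend(r, p, invert=False, valid=valid)
)
register_backend(
    "builtin-lumen", lambda r, p, valid=None: _threshold_backend(r, p, invert=True, valid=valid)
)


def segment_plane(
    image: PlaneImage,
    model: SegmentationModelSpec,
    diameter_override_um: float | None = None,
) -> SegmentationOutcome:
    """Run the model's backend on a plane raster.

    ``diameter_override_um`` substitutes the model's diameter prior, used by
    the troubleshooting diameter sweep.
    """
    if image.raster.size == 0:
        raise ValueError("empty plane image")
    try:
        backend = _BACKENDS[model.backend_key]
    except KeyError:
        raise RuntimeError(
            f"segmentation backend {model.backend_key!r} is not registered "
            "(plugin unavailable)"
        ) from None
    prior_um = diameter_override_um if diameter_override_um is not None else model.diameter_prior_um
    prior_px = prior_um / image.pixel_pitch_um
    valid = ~image.oob
    try:
        labels = np.asarray(backend(image.raster, prior_px, valid=valid))
    except TypeError:  # plugin backends may not accept the valid mask
        labels = np.asarray(backend(image.raster, prior_px))
    # relabel to contiguous positive integers
    labels, n = ndi.label(labels > 0)
    return SegmentationOutcome(labels=labels.astype(np.int32), model_id=model.model_id, success=n > 0)


def select_center_mask(
    outcome: SegmentationOutcome, image: PlaneImage
) -> CrossSectionMask | None:
    """Return the labeled object containing the plane-center pixel, or None."""
    labels = outcome.labels
    r0, c0 = labels.shape[0] // 2, labels.shape[1] // 2
    lab = labels[r0, c0]
    if lab == 0:
        return None
    mask = labels == lab
    return mask_statistics(mask, image, outcome.model_id)


def mask_statistics(
    mask: np.ndarray, image: PlaneImage, model_id: str = ""
) -> CrossSectionMask:
    """Compute centroid, area, equivalent diameter, and ellipse fit of a mask."""
    pitch = image.pixel_pitch_um
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    cr, cc = rows.mean(), cols.mean()
    area = rows.size * pitch**2
    d_eq = 2.0 * np.sqrt(area / np.pi)
    major = minor = d_eq / 2.0
    phi = 0.0
    ecc = 0.0
    if rows.size >= 5:
        try:
            major, minor, phi, ecc = fit_ellipse_pixels(rows, cols, pitch)
        except ValueError:
            pass  # degenerate mask: fall back to circular statistics
    centroid_world = image.plane.pixel_to_world(cr, cc)
    return CrossSectionMask(
        mask=mask,
        plane_image=image,
        centroid_px=np.array([cr, cc]),
        centroid_um=np.asarray(centroid_world, float).reshape(3),
        area_um2=float(area),
        equiv_diameter_um=float(d_eq),
        major_um=float(major),
        minor_um=float(minor),
        phi_rad=float(phi),
        eccentricity=float(ecc),
    )


def fit_ellipse(mask_obj: CrossSectionMask) -> tuple[float, float, float, float]:
    """Second-moment ellipse of a cross-section: (major, minor, phi, e).

    Semi-axes are in µm; phi is the angle of the major axis from the plane's
    u axis (pixel rows), in radians.
    """
    rows, cols = np.nonzero(mask_obj.mask)
    if rows.size < 5:
        raise ValueError("mask too small for an ellipse fit (< 5 pixels)")
    return fit_ellipse_pixels(rows, cols, mask_obj.plane_image.pixel_pitch_um)


def fit_ellipse_pixels(
    rows: np.ndarray, cols: np.ndarray, pitch: float
) -> tuple[float, float, float, float]:
    u = rows * pitch
    v = cols * pitch
    mu20 = np.var(u) + pitch**2 / 12.0  # pixel extent regularizes thin masks
    mu02 = np.var(v) + pitch**2 / 12.0
    mu11 = np.mean((u - u.mean()) * (v - v.mean()))
    common = np.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11**2)
    lam1 = (mu20 + mu02) / 2.0 + common
    lam2 = (mu20 + mu02) / 2.0 - common
    if lam2 <= 0:
        raise ValueError("degenerate (collinear) mask")
    major = 2.0 * np.sqrt(lam1)
    minor = 2.0 * np.sqrt(lam2)
    phi = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    ecc = float(np.sqrt(max(1.0 - (minor / major) ** 2, 0.0)))
    return float(major), float(minor), float(phi), ecc


# ---------------------------------------------------------------------------
# Training-frame selection
# ---------------------------------------------------------------------------


def _ms_ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Multi-scale SSIM: mean of SSIM at dyadic scales 1x, 2x, 4x."""
    vals = []
    for f in (1, 2, 4):
        if min(a.shape) // f < 8:
            break
        aa = downscale_local_mean(a, (f, f)) if f > 1 else a
        bb = downscale_local_mean(b, (f, f)) if f > 1 else b
        rng = max(float(aa.max() - aa.min()), float(bb.max() - bb.min()), 1e-9)
        vals.append(structural_similarity(aa, bb, data_range=rng))
    if not vals:
        rng = max(float(a.max() - a.min()), float(b.max() - b.min()), 1e-9)
        win = min(7, min(a.shape) | 1)
        vals = [structural_similarity(a, b, data_range=rng, win_size=win)]
    return float(np.mean(vals))


def select_training_frames(
    planes: list[PlaneImage] | list[np.ndarray],
    params: FrameSelectionParams,
    frame_spacing: float = 1.0,
) -> list[int]:
    """Greedy diversity scan over frames ordered along a centerline.

    Frame i is kept iff (1 - SSIM vs previously kept frame) >= alpha AND
    (1 - mean SSIM vs all kept frames) >= beta AND the distance since the
    last kept frame is >= t.  The first frame is always kept.
    """
    rasters = [p.raster if isinstance(p, PlaneImage) else np.asarray(p, np.float32) for p in planes]
    if not rasters:
        return []
    kept = [0]
    for i in range(1, len(rasters)):
        if (i - kept[-1]) * frame_spacing < params.t:
            continue
        local = 1.0 - _ms_ssim(rasters[i], rasters[kept[-1]])
        if local < params.alpha:
            continue
        global_change = 1.0 - float(np.mean([_ms_ssim(rasters[i], rasters[k]) for k in kept]))
        if global_change < params.beta:
            continue
        kept.append(i)
    return kept
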