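"""Hierarchical staging of tubule cross-sections and wave counting.

Cross-sections of seminiferous tubules are classified into three visually
distinct DNA-staining classes: ``dark`` (no bright spermatozoa signal),
``sparse_clusters`` (many small bright clusters), and ``dense_clusters``
(a few large bright clusters at the epithelial rim).  The classifier is
hierarchical with four parameters:

* a — first intensity threshold as a multiplier of the median intensity
  within the cross-section mask (a raw-intensity variant is configurable);
* b — area fraction below which a frame is ``dark``;
* c — second, raw intensity threshold used to re-segment non-dark frames;
* d — cluster-dominance threshold: the frame is ``sparse_clusters`` when the
  two largest 8-connected bright components hold less than fraction d of the
  total bright area, else ``dense_clusters``.

Labels are smoothed along the tubule with a rolling modal window (default
2 mm) before waves are counted.  A complete wave is three consecutive label
runs covering all three classes in one consistent cyclic direction
(dark -> sparse -> dense -> dark); a reversal is a change of traversal
direction between adjacent run transitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from sklearn.metrics import f1_score

from .segmentation import CrossSectionMask
from .volume_io import PlaneImage

__all__ = [
    "WaveClassifierParams",
    "StageSequence",
    "classify_frame",
    "smooth_labels",
    "count_waves",
    "calibrate_params",
]

CLASSES = ("dark", "sparse_clusters", "dense_clusters")
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class WaveClassifierParams:
    a: float = 2.5  # threshold-1 multiplier of the in-mask median intensity
    b: float = 0.02  # dark-class area fraction
    c: float = 86.0  # threshold-2, raw intensity
    d: float = 0.62  # cluster-dominance fraction
    smoothing_window_um: float = 2000.0
    a_is_absolute: bool = False  # treat `a` as a raw intensity instead

    def __post_init__(self) -> None:
        if not (0.0 <= self.b <= 1.0 and 0.0 <= self.d <= 1.0):
            raise ValueError("b and d must be in [0, 1]")
        if self.a <= 0 or self.c <= 0:
            raise ValueError("a and c must be positive")


@dataclass
class StageSequence:
    arc_um: np.ndarray
    raw: list[str]
    smoothed: list[str] = field(default_factory=list)
    waves: list[tuple[float, float, str]] = field(default_factory=list)  # (start, end, direction)
    reversals: list[float] = field(default_factory=list)


def classify_frame(
    frame: PlaneImage | np.ndarray,
    mask: CrossSectionMask | np.ndarray,
    params: WaveClassifierParams,
) -> str:
    """Classify one cross-section frame; see module docstring for the rule."""
    raster = frame.raster if isinstance(frame, PlaneImage) else np.asarray(frame, np.float32)
    m = mask.mask if isinstance(mask, CrossSectionMask) else np.asarray(mask, bool)
    area = int(np.count_nonzero(m))
    if area == 0:
        raise ValueError("empty cross-section mask")
    thr1 = params.a if params.a_is_absolute else params.a * float(np.median(raster[m]))
    bright1 = (raster > thr1) & m
    if np.count_nonzero(bright1) / area < params.b:
        return "dark"
    bright2 = (raster > params.c) & m
    total = int(np.count_nonzero(bright2))
    if total == 0:
        return "dark"
    labels, n = ndi.label(bright2, structure=_EIGHT)
    sizes = np.sort(ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1)))[::-1]
    top2 = float(sizes[:2].sum())
    return "sparse_clusters" if top2 / total < params.d else "dense_clusters"


def smooth_labels(seq: StageSequence, window_um: float = 2000.0) -> StageSequence:
    """Rolling modal smoothing of raw labels along the tubule axis.

    The smoothed label at arc s is the modal raw label within
    [s - w/2, s + w/2]; ties keep the previous smoothed label.
    """
    arcs = np.asarray(seq.arc_um, float)
    raw_idx = np.array([_CLASS_INDEX[r] for r in seq.raw])
    smoothed: list[str] = []
    half = window_um / 2.0
    prev = raw_idx[0] if len(raw_idx) else 0
    for i, s in enumerate(arcs):
        sel = (arcs >= s - half) & (arcs <= s + half)
        counts = np.bincount(raw_idx[sel], minlength=3)
        best = counts.max()
        winners = np.flatnonzero(counts == best)
        pick = prev if prev in winners else int(winners[0])
        smoothed.append(CLASSES[pick])
        prev = pick
    seq.smoothed = smoothed
    return seq


def _runs(labels: list[str], arcs: np.ndarray) -> list[tuple[str, float, float]]:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], float(arcs[start]), float(arcs[i - 1])))
            start = i
    return runs


def _direction(a: str, b: str) -> int:
    """+1 for a forward cyclic transition dark->sparse->dense->dark, -1 reverse."""
    diff = (_CLASS_INDEX[b] - _CLASS_INDEX[a]) % 3
    return 1 if diff == 1 else -1


def count_waves(seq: StageSequence) -> StageSequence:
    """Count complete waves and reversals on the smoothed label sequence."""
    labels = seq.smoothed if seq.smoothed else seq.raw
    arcs = np.asarray(seq.arc_um, float)
    runs = _runs(labels, arcs)
    waves: list[tuple[float, float, str]] = []
    i = 0
    while i + 2 < len(runs):
        trio = runs[i : i + 3]
        classes = {r[0] for r in trio}
        d1 = _direction(trio[0][0], trio[1][0])
        d2 = _direction(trio[1][0], trio[2][0])
        if len(classes) == 3 and d1 == d2:
            waves.append((trio[0][1], trio[2][2], "forward" if d1 > 0 else "reverse"))
            i += 3
        else:
            i += 1
    reversals: list[float] = []
    dirs = [_direction(runs[k][0], runs[k + 1][0]) for k in range(len(runs) - 1)]
    for k in range(1, len(dirs)):
        if dirs[k] != dirs[k - 1]:
            reversals.append(runs[k + 1][1])  # arc where the direction flips
    seq.waves = waves
    seq.reversals = reversals
    return seq


def calibrate_params(
    frames: list[PlaneImage | np.ndarray],
    masks: list[CrossSectionMask | np.ndarray],
    labels: list[str],
    a_grid,
    b_grid,
    c_grid,
    d_grid,
    a_is_absolute: bool = False,
) -> tuple[WaveClassifierParams, float]:
    """Exhaustive grid search maximizing macro-F1 of classify_frame.

    Ties break toward smaller a, then smaller c.  Per-frame features are
    cached per (a, c) so the grid scales with the threshold grids rather than
    the full Cartesian product.
    """
    a_grid = sorted(set(float(x) for x in a_grid))
    b_grid = sorted(set(float(x) for x in b_grid))
    c_grid = sorted(set(float(x) for x in c_grid))
    d_grid = sorted(set(float(x) for x in d_grid))
    if not (a_grid and b_grid and c_grid and d_grid):
        raise ValueError("empty parameter grid")
    if len(set(labels)) < 2:
        raise ValueError("calibration needs >= 2 classes in the labels")

    rasters = [f.raster if isinstance(f, PlaneImage) else np.asarray(f, np.float32) for f in frames]
    ms = [m.mask if isinstance(m, CrossSectionMask) else np.asarray(m, bool) for m in masks]
    areas = np.array([np.count_nonzero(m) for m in ms], float)
    medians = np.array([np.median(r[m]) for r, m in zip(rasters, ms)])

    # fraction of in-mask pixels above threshold-1, per a
    frac1 = {}
    for a in a_grid:
        thr = np.full(len(rasters), a) if a_is_absolute else a * medians
        frac1[a] = np.array(
            [np.count_nonzero((r > t) & m) / ar for r, m, t, ar in zip(rasters, ms, thr, areas)]
        )
    # cluster dominance ratio per c (NaN when no bright pixels)
    ratio = {}
    for c in c_grid:
        vals = np.empty(len(rasters))
        for i, (r, m) in enumerate(zip(rasters, ms)):
            bright = (r > c) & m
            total = int(np.count_nonzero(bright))
            if total == 0:
                vals[i] = np.nan
                continue
            lab, n = ndi.label(bright, structure=_EIGHT)
            sizes = np.sort(ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1)))[::-1]
            vals[i] = float(sizes[:2].sum()) / total
        ratio[c] = vals

    y_true = np.array([_CLASS_INDEX[l] for l in labels])
    best: tuple[float, float, float, WaveClassifierParams] | None = None
    for a, b, c, d in itertools.product(a_grid, b_grid, c_grid, d_grid):
        pred = np.full(len(rasters), _CLASS_INDEX["dense_clusters"])
        dark = (frac1[a] < b) | np.isnan(ratio[c])
        sparse = ~dark & (ratio[c] < d)
        pred[dark] = _CLASS_INDEX["dark"]
        pred[sparse] = _CLASS_INDEX["sparse_clusters"]
        f1 = float(f1_score(y_true, pred, average="macro", zero_division=0))
        key = (f1, -a, -c)
        if best is None or key > best[:3]:
            best = (f1, -a, -c, WaveClassifierParams(a=a, b=b, c=c, d=d, a_is_absolute=a_is_absolute))
    assert best is not None
    return best[3], best[0]
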