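"""Synthetic 3D tubule phantoms with complete ground truth.

The generator emulates the imaging regimes a centerline tracker must survive
in cleared-tissue light-sheet volumes of renal and seminiferous tubules:
bright tubule walls around a dim lumen, abrupt diameter transitions
(~40 µm proximal segments stepping down to ~16 µm thin segments), tight
bends, branching with optional reconnection, planted nuclei for cytometry,
and periodic staining patterns along the tube for wave staging.

Walls are rendered from the distance of each voxel to a dense resampling of
the centerline (step <= 1/4 voxel), which is exact up to that resampling for
free-form curves.  Noise is additive Gaussian, clipped at zero.  With a fixed
``rng_seed`` the output volume is bit-identical between calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import orthonormal_basis, polyline_arclength, resample_polyline, transport_frame, unit
from .volume_io import VoxelGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "BranchSpec",
    "NucleiSpec",
    "WaveSpec",
    "make_tube_phantom",
    "make_branching_phantom",
    "make_wave_phantom",
    "save_truth",
]

WAVE_CLASSES = ("dark", "sparse_clusters", "dense_clusters")


@dataclass
class NucleiSpec:
    linear_density_per_um: float
    radius_um: float = 4.0
    in_lumen_fraction: float = 1.0


@dataclass
class WaveSpec:
    """Ordered class pattern along the tube with per-class arc extents.

    Each pattern entry is (class name, extent in µm).  The three classes are
    rendered as synthetic stand-ins for DNA staining patterns: ``dark`` has no
    bright objects; ``sparse_clusters`` carries many thin bright rods in the
    epithelial wall; ``dense_clusters`` carries a few large bright rods at the
    epithelial rim.
    """

    pattern: list[tuple[str, float]]
    object_intensity: float = 150.0
    sparse_count: int = 12
    sparse_radius_um: float = 2.5
    dense_count: int = 2
    dense_radius_um: float = 10.0


@dataclass
class BranchSpec:
    attach_arclength_um: float
    child: "PhantomSpec"
    reconnect_at_um: float | None = None


@dataclass
class PhantomSpec:
    """Parametric description of one tubular structure and its rendering."""

    centerline_model: dict
    radius_profile: dict
    volume_shape: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_model: dict = field(
        default_factory=lambda: {"kind": "wall_bright", "wall_thickness_um": 6.0}
    )
    contrast: float = 5.0
    background: float = 20.0
    noise_sd: float = 5.0
    branch_specs: list[BranchSpec] = field(default_factory=list)
    nuclei_spec: NucleiSpec | None = None
    wave_spec: WaveSpec | None = None
    gaps_um: list[tuple[float, float]] = field(default_factory=list)
    """Arc intervals on the main tube where the stain signal is absent
    (occlusion/labeling failure); the truth mask still includes the tube."""
    rng_seed: int = 0


@dataclass
class PlantedNucleus:
    centroid_um: np.ndarray
    radius_um: float
    tube_id: int
    in_lumen: bool


@dataclass
class TubeTruth:
    tube_id: int
    points_um: np.ndarray  # dense centerline (N, 3) world µm
    arcs_um: np.ndarray
    radii_um: np.ndarray

    @property
    def length_um(self) -> float:
        return float(self.arcs_um[-1])


@dataclass
class PhantomTruth:
    tubes: list[TubeTruth]
    mask: np.ndarray  # bool, voxel ground truth (dist <= radius)
    nuclei: list[PlantedNucleus] = field(default_factory=list)
    class_segments: list[tuple[float, float, str]] = field(default_factory=list)
    junctions_um: list[np.ndarray] = field(default_factory=list)
    reconnections_um: list[np.ndarray] = field(default_factory=list)
    nuclei_volume: VoxelGrid | None = None

    @property
    def centerline(self) -> TubeTruth:
        return self.tubes[0]

    def label_at(self, s_um: float) -> str | None:
        for s0, s1, lab in self.class_segments:
            if s0 <= s_um < s1:
                return lab
        if self.class_segments and abs(s_um - self.class_segments[-1][1]) < 1e-6:
            return self.class_segments[-1][2]
        return None


# ---------------------------------------------------------------------------
# Centerline models
# ---------------------------------------------------------------------------


def _centerline_points(model: dict, step: float, rng: np.random.Generator) -> np.ndarray:
    kind = model["kind"].replace("-", "_")
    if kind == "line":
        start = np.asarray(model["start"], float)
        d = unit(np.asarray(model["direction"], float))
        L = float(model["length"])
        n = max(int(np.ceil(L / step)) + 1, 2)
        t = np.linspace(0.0, L, n)
        return start + t[:, None] * d
    if kind == "arc":
        # circular arc in the plane perpendicular to `plane_normal`, starting at
        # `start` with tangent `tangent`, turning `turn_deg` at radius R_c.
        start = np.asarray(model["start"], float)
        tangent = unit(np.asarray(model["tangent"], float))
        normal = unit(np.asarray(model.get("plane_normal", (1.0, 0.0, 0.0)), float))
        R = float(model["radius"])
        turn = np.deg2rad(float(model["turn_deg"]))
        to_center = unit(np.cross(normal, tangent))
        center = start + R * to_center
        n = max(int(np.ceil(abs(turn) * R / step)) + 1, 2)
        ang = np.linspace(0.0, turn, n)
        r0 = start - center
        pts = center + np.outer(np.cos(ang), r0) + np.outer(np.sin(ang), np.cross(normal, r0))
        return pts
    if kind == "helix":
        R = float(model["radius"])
        c = float(model["pitch_c"])  # z advance per radian
        turns = float(model.get("turns", 2.0))
        center = np.asarray(model.get("center", (0.0, 0.0, 0.0)), float)
        n = max(int(np.ceil(turns * 2 * np.pi * np.sqrt(R**2 + c**2) / step)) + 1, 2)
        t = np.linspace(0.0, turns * 2 * np.pi, n)
        # axis along z (axis 0): (z, y, x) = (c t, R sin t, R cos t)
        return center + np.stack([c * t, R * np.sin(t), R * np.cos(t)], axis=1)
    if kind == "sine":
        start = np.asarray(model["start"], float)
        L = float(model["length"])
        amp = float(model["amplitude"])
        period = float(model["period"])
        n = max(int(np.ceil(1.5 * L / step)) + 1, 2)
        x = np.linspace(0.0, L, n)
        pts = start + np.stack(
            [np.zeros_like(x), amp * np.sin(2 * np.pi * x / period), x], axis=1
        )
        pts, _ = resample_polyline(pts, step)
        return pts
    if kind == "piecewise_polyline":
        pts = np.asarray(model["points"], float)
        pts, _ = resample_polyline(pts, step)
        return pts
    if kind == "random_smooth_walk":
        L = float(model["length"])
        kappa_max = float(model["max_curvature_per_um"])
        start = np.asarray(model["start"], float)
        d = unit(np.asarray(model.get("direction", (0.0, 0.0, 1.0)), float))
        coarse = max(step * 20, 2.0)
        n = int(np.ceil(L / coarse))
        pts = [start]
        for _ in range(n):
            # bounded random turn per segment keeps curvature under the cap
            max_turn = kappa_max * coarse
            axis = unit(rng.normal(size=3))
            axis = unit(np.cross(axis, d)) if np.linalg.norm(np.cross(axis, d)) > 1e-9 else unit(np.cross((1, 0, 0), d))
            angle = rng.uniform(-max_turn, max_turn)
            from .geometry import rotate_about_axis

            d = unit(rotate_about_axis(d, axis, angle))
            pts.append(pts[-1] + d * coarse)
        pts = np.asarray(pts)
        pts, _ = resample_polyline(pts, step)
        return pts
    raise ValueError(f"unknown centerline model: {model['kind']!r}")


def _radius_at(profile: dict, arcs: np.ndarray) -> np.ndarray:
    kind = profile["kind"]
    if kind == "constant":
        return np.full_like(arcs, float(profile["radius"]))
    if kind == "linear":
        return np.interp(arcs, [0.0, arcs[-1]], [float(profile["r0"]), float(profile["r1"])])
    if kind == "steps":
        steps = sorted(profile["steps"])  # [(arc_um, radius_um), ...]
        out = np.full_like(arcs, float(steps[0][1]))
        for s, r in steps:
            out[arcs >= s] = float(r)
        return out
    raise ValueError(f"unknown radius profile: {kind!r}")


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------


def _rmf_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing (u, v) frames along a dense polyline."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n0, u, v = orthonormal_basis(tangents[0])
    us = np.empty_like(points)
    vs = np.empty_like(points)
    us[0], vs[0] = u, v
    for i in range(1, len(points)):
        u, v = transport_frame(us[i - 1], vs[i - 1], tangents[i - 1], tangents[i])
        us[i], vs[i] = u, v
    return us, vs


class _TubeGeometry:
    """Dense centerline + radii for one tube, with bounds/collision checks."""

    def __init__(self, tube_id: int, points: np.ndarray, radius_profile: dict):
        self.tube_id = tube_id
        self.points = points
        self.arcs = polyline_arclength(points)
        self.radii = _radius_at(radius_profile, self.arcs)

    @property
    def length_um(self) -> float:
        return float(self.arcs[-1])

    def point_at(self, s: float) -> np.ndarray:
        out = np.empty(3)
        for k in range(3):
            out[k] = np.interp(s, self.arcs, self.points[:, k])
        return out


def _check_bounds(geom: _TubeGeometry, volume_shape, spacing) -> None:
    hi = (np.asarray(volume_shape) - 1) * np.asarray(spacing)
    margin = geom.radii[:, None]
    if np.any(geom.points < margin) or np.any(geom.points > hi - margin):
        bad = np.argmax(np.any((geom.points < margin) | (geom.points > hi - margin), axis=1))
        raise ValueError(
            f"centerline leaves the volume: tube {geom.tube_id} point {geom.points[bad]} "
            f"is closer than one radius ({geom.radii[bad]:.1f} µm) to the bounds {hi}"
        )


def _build(spec: PhantomSpec) -> tuple[VoxelGrid, PhantomTruth]:
    spacing = np.asarray(spec.voxel_spacing, float)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    rng = np.random.default_rng(spec.rng_seed)
    step = float(min(spacing)) / 4.0

    # --- geometry ---------------------------------------------------------
    tubes: list[_TubeGeometry] = []
    main_pts = _centerline_points(spec.centerline_model, step, rng)
    main = _TubeGeometry(0, main_pts, spec.radius_profile)
    tubes.append(main)
    if float(np.min(main.radii)) < 2.0 * float(max(spacing[1], spacing[2])):
        raise ValueError("tube radius must be >= 2x the max lateral voxel spacing")
    _check_bounds(main, spec.volume_shape, spacing)

    junctions: list[np.ndarray] = []
    reconnections: list[np.ndarray] = []
    parent_tree = cKDTree(main.points)
    for k, br in enumerate(spec.branch_specs, start=1):
        child_pts = _centerline_points(br.child.centerline_model, step, rng)
        # weld the child endpoints onto the parent centerline
        child_pts = child_pts + (main.point_at(br.attach_arclength_um) - child_pts[0])
        if br.reconnect_at_um is not None:
            target = main.point_at(br.reconnect_at_um)
            drift = target - child_pts[-1]
            w = np.linspace(0.0, 1.0, len(child_pts))[:, None]
            child_pts = child_pts + w * drift
        child = _TubeGeometry(k, child_pts, br.child.radius_profile)
        _check_bounds(child, spec.volume_shape, spacing)
        # collision check away from the welded ends
        r_child = float(np.max(child.radii))
        free = child.arcs > 4 * r_child
        if br.reconnect_at_um is not None:
            free &= child.arcs < child.arcs[-1] - 4 * r_child
        if np.any(free):
            d, idx = parent_tree.query(child.points[free])
            clearance = child.radii[free] + main.radii[idx]
            if np.any(d < clearance):
                raise ValueError(
                    f"branch {k} collides with an unrelated region of its parent tube"
                )
        tubes.append(child)
        junctions.append(main.point_at(br.attach_arclength_um))
        if br.reconnect_at_um is not None:
            reconnections.append(main.point_at(br.reconnect_at_um))

    # --- distance field ----------------------------------------------------
    all_pts = np.concatenate([t.points for t in tubes])
    all_radii = np.concatenate([t.radii for t in tubes])

    shape = tuple(spec.volume_shape)
    imodel = spec.intensity_model
    wall_t = float(imodel.get("wall_thickness_um", 6.0))
    reach = float(np.max(all_radii)) + 3.0 * float(max(spacing))

    lo_idx = np.maximum(np.floor((all_pts.min(axis=0) - reach) / spacing), 0).astype(int)
    hi_idx = np.minimum(
        np.ceil((all_pts.max(axis=0) + reach) / spacing), np.asarray(shape) - 1
    ).astype(int)
    zz, yy, xx = np.meshgrid(
        *[np.arange(lo_idx[a], hi_idx[a] + 1) for a in range(3)], indexing="ij"
    )
    vox_idx = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    vox_world = vox_idx * spacing

    # union over tubes: a voxel is lumen if it lies in ANY tube's lumen
    # (fused lumens connect at junctions), wall if inside a tube but in no
    # lumen — this keeps the outer wall closed across branch points
    inside = np.zeros(len(vox_world), dtype=bool)
    lumen = np.zeros(len(vox_world), dtype=bool)
    dist = None
    nearest = None
    for t in tubes:
        tree_t = cKDTree(t.points)
        d_t, i_t = tree_t.query(vox_world, workers=-1)
        r_t = t.radii[i_t]
        inside |= d_t <= r_t
        lumen |= d_t < r_t - wall_t
        if t.tube_id == 0:
            dist, nearest = d_t, i_t  # main-tube frame for nuclei/wave objects
    mask = np.zeros(shape, dtype=bool)
    mask[vox_idx[inside, 0], vox_idx[inside, 1], vox_idx[inside, 2]] = True
    r_local = tubes[0].radii[nearest]

    # planted signal gaps: suppress foreground rendering on main-tube arcs
    rendered = np.ones(len(vox_world), dtype=bool)
    for g0, g1 in spec.gaps_um:
        s_vox = tubes[0].arcs[nearest]
        rendered &= ~((s_vox >= g0) & (s_vox <= g1) & (dist <= r_local + wall_t))

    volume = np.full(shape, float(spec.background), dtype=np.float32)
    fg_value = float(spec.contrast * spec.background)
    if imodel["kind"] == "wall_bright":
        lumen_value = float(imodel.get("lumen", spec.background))
        wall = inside & ~lumen & rendered
        lum = inside & lumen & rendered
        volume[vox_idx[wall, 0], vox_idx[wall, 1], vox_idx[wall, 2]] = fg_value
        volume[vox_idx[lum, 0], vox_idx[lum, 1], vox_idx[lum, 2]] = lumen_value
    elif imodel["kind"] == "solid_bright":
        fg = inside & rendered
        volume[vox_idx[fg, 0], vox_idx[fg, 1], vox_idx[fg, 2]] = fg_value
    else:
        raise ValueError(f"unknown intensity model: {imodel['kind']!r}")

    # --- wave staining pattern ---------------------------------------------
    class_segments: list[tuple[float, float, str]] = []
    if spec.wave_spec is not None:
        ws = spec.wave_spec
        total = sum(e for _, e in ws.pattern)
        if total > main.length_um + 1e-6:
            raise ValueError(
                f"wave pattern extent ({total:.0f} µm) exceeds tube length "
                f"({main.length_um:.0f} µm)"
            )
        s0 = 0.0
        for name, extent in ws.pattern:
            if name not in WAVE_CLASSES:
                raise ValueError(f"unknown wave class {name!r}")
            class_segments.append((s0, s0 + extent, name))
            s0 += extent
        us, vs = _rmf_frames(main.points)
        # candidate voxels: near the wall of the main tube
        near_wall = (dist >= r_local - wall_t - ws.dense_radius_um) & (
            dist <= r_local + ws.dense_radius_um
        )
        cand = np.flatnonzero(near_wall)
        if cand.size:
            ni = nearest[cand]
            offs = vox_world[cand] - main.points[ni]
            pu = np.einsum("ij,ij->i", offs, us[ni])
            pv = np.einsum("ij,ij->i", offs, vs[ni])
            s_here = main.arcs[ni]
            paint = np.zeros(cand.size, dtype=bool)
            for s_start, s_end, name in class_segments:
                in_seg = (s_here >= s_start) & (s_here < s_end)
                if not np.any(in_seg) or name == "dark":
                    continue
                if name == "sparse_clusters":
                    count, rho = ws.sparse_count, ws.sparse_radius_um
                else:
                    count, rho = ws.dense_count, ws.dense_radius_um
                sel = np.flatnonzero(in_seg)
                r_mid = r_local[cand[sel]] - wall_t / 2.0
                thetas = 2 * np.pi * np.arange(count) / count + (s_start * 0.01)
                hit = np.zeros(sel.size, dtype=bool)
                for th in thetas:
                    cu = r_mid * np.cos(th)
                    cv = r_mid * np.sin(th)
                    d2 = (pu[sel] - cu) ** 2 + (pv[sel] - cv) ** 2
                    hit |= d2 < rho**2
                paint[sel] |= hit
            pidx = vox_idx[cand[paint]]
            volume[pidx[:, 0], pidx[:, 1], pidx[:, 2]] = ws.object_intensity

    # --- nuclei -------------------------------------------------------------
    nuclei: list[PlantedNucleus] = []
    nuclei_volume = None
    if spec.nuclei_spec is not None:
        ns = spec.nuclei_spec
        nuc = np.full(shape, 10.0, dtype=np.float32)
        us, vs = _rmf_frames(main.points)
        n_total = int(round(ns.linear_density_per_um * main.length_um))
        n_lumen = int(round(ns.in_lumen_fraction * n_total))
        # rejection sampling keeps nuclei separated so they stay resolvable
        min_sep = 2.0 * ns.radius_um + 2.0
        placed: list[np.ndarray] = []
        j = 0
        attempts = 0
        while j < n_total and attempts < 200 * n_total:
            attempts += 1
            s = rng.uniform(2 * ns.radius_um, main.length_um - 2 * ns.radius_um)
            i = min(int(np.searchsorted(main.arcs, s)), len(main.points) - 1)
            r_here = main.radii[i]
            in_lumen = j < n_lumen
            theta = rng.uniform(0, 2 * np.pi)
            if in_lumen:
                rmax = max(r_here - wall_t - ns.radius_um - 0.5, 0.0)
                rad = rng.uniform(0, rmax)
            else:
                rad = r_here + ns.radius_um + 1.0 + rng.uniform(0, 2 * ns.radius_um)
            c = main.points[i] + rad * (np.cos(theta) * us[i] + np.sin(theta) * vs[i])
            ci = c / spacing
            if np.any(ci < 1) or np.any(ci > np.asarray(shape) - 2):
                continue
            if placed and np.min(np.linalg.norm(np.asarray(placed) - c, axis=1)) < min_sep:
                continue
            placed.append(c)
            _paint_ball(nuc, c, ns.radius_um, spacing, 150.0)
            nuclei.append(PlantedNucleus(c, ns.radius_um, 0 if in_lumen else -1, in_lumen))
            j += 1
        nuclei.sort(key=lambda n: float(n.centroid_um[0]))
        nuc += rng.normal(0.0, 3.0, size=shape).astype(np.float32)
        np.clip(nuc, 0.0, None, out=nuc)
        nuclei_volume = VoxelGrid(nuc, spacing=spacing, channel_id="nuclei")

    # --- noise --------------------------------------------------------------
    if spec.noise_sd > 0:
        volume += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        np.clip(volume, 0.0, None, out=volume)

    grid = VoxelGrid(volume, spacing=spacing, channel_id="raw")
    truth = PhantomTruth(
        tubes=[
            TubeTruth(t.tube_id, t.points, t.arcs, t.radii) for t in tubes
        ],
        mask=mask,
        nuclei=nuclei,
        class_segments=class_segments,
        junctions_um=junctions,
        reconnections_um=reconnections,
        nuclei_volume=nuclei_volume,
    )
    return grid, truth


def _paint_ball(
    vol: np.ndarray, center_um: np.ndarray, radius_um: float, spacing: np.ndarray, value: float
) -> None:
    lo = np.maximum(np.floor((center_um - radius_um) / spacing), 0).astype(int)
    hi = np.minimum(np.ceil((center_um + radius_um) / spacing), np.asarray(vol.shape) - 1).astype(int)
    zz, yy, xx = np.meshgrid(
        *[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij"
    )
    d2 = (
        (zz * spacing[0] - center_um[0]) ** 2
        + (yy * spacing[1] - center_um[1]) ** 2
        + (xx * spacing[2] - center_um[2]) ** 2
    )
    sel = d2 <= radius_um**2
    vol[zz[sel], yy[sel], xx[sel]] = value


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def make_tube_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, PhantomTruth]:
    """Render a single-tube phantom (any centerline model) with ground truth."""
    return _build(spec)


def make_branching_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, PhantomTruth]:
    """Render a phantom with one or more branch tubes attached to the parent."""
    if not spec.branch_specs:
        raise ValueError("branching phantom requires non-empty branch_specs")
    return _build(spec)


def make_wave_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, PhantomTruth]:
    """Render a phantom with a periodic staining pattern along the main tube."""
    if spec.wave_spec is None:
        raise ValueError("wave phantom requires wave_spec")
    return _build(spec)


def save_truth(truth: PhantomTruth, path: str | Path) -> None:
    """Write truth as JSON (centerlines, nuclei, labels) + a mask TIFF."""
    import tifffile

    path = Path(path)
    payload = {
        "tubes": [
            {
                "tube_id": t.tube_id,
                "points_um": t.points_um[:: max(len(t.points_um) // 2000, 1)].tolist(),
                "radii_um": t.radii_um[:: max(len(t.radii_um) // 2000, 1)].tolist(),
            }
            for t in truth.tubes
        ],
        "nuclei": [
            {
                "centroid_um": n.centroid_um.tolist(),
                "radius_um": n.radius_um,
                "tube_id": n.tube_id,
                "in_lumen": n.in_lumen,
            }
            for n in truth.nuclei
        ],
        "class_segments": [[s0, s1, lab] for s0, s1, lab in truth.class_segments],
        "junctions_um": [j.tolist() for j in truth.junctions_um],
        "reconnections_um": [j.tolist() for j in truth.reconnections_um],
    }
    path.with_suffix(".json").write_text(json.dumps(payload))
    tifffile.imwrite(str(path.with_suffix(".mask.tif")), truth.mask.astype(np.uint8))
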