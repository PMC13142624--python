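"""Volumes, multiscale pyramids, and oblique plane resampling.

A :class:`VoxelGrid` is a single resolution level of a 3D microscopy channel:
a scalar raster plus physical voxel spacing in micrometres, axis order
(z, y, x).  :func:`sample_plane` resamples an arbitrarily oriented square
plane out of the volume with trilinear interpolation, the primitive on which
orthogonal cross-section tracking is built.

Multiscale volumes are stored as zarr groups laid out like OME-NGFF
multiscale images (one array per level named "0", "1", ..., 2x downsampling
per level, per-level scale transforms in the group attributes), plus
single-scale TIFF and HDF5 readers for small fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .geometry import orthonormal_basis

__all__ = [
    "VoxelGrid",
    "MultiscaleVolume",
    "OrientedPlane",
    "PlaneImage",
    "load_volume",
    "sample_plane",
    "extract_local_slab",
    "write_multiscale_zarr",
    "write_tiff",
    "write_hdf5",
]


@dataclass
class VoxelGrid:
    """3D intensity raster with physical spacing (µm) in (z, y, x) order."""

    intensities: np.ndarray
    spacing: np.ndarray  # µm per axis (z, y, x)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    channel_id: str = "raw"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D raster")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if min(self.intensities.shape) < 1:
            raise ValueError("shape must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the volume in µm per axis."""
        return (np.asarray(self.shape) - 1) * self.spacing

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def contains_world(self, world: np.ndarray, margin_um: float = 0.0) -> bool:
        idx = self.world_to_index(world)
        lo = margin_um / self.spacing
        hi = np.asarray(self.shape) - 1 - lo
        return bool(np.all(idx >= lo) and np.all(idx <= hi))


@dataclass
class MultiscaleVolume:
    """Ordered pyramid of VoxelGrids; level k+1 spacing = level k * factor."""

    levels: list[VoxelGrid]
    factor: int = 2
    chunk_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        for k in range(1, len(self.levels)):
            expected = self.levels[k - 1].spacing * self.factor
            if not np.allclose(self.levels[k].spacing, expected):
                raise ValueError("pyramid spacing inconsistent with downsample factor")

    def __getitem__(self, level: int) -> VoxelGrid:
        return self.levels[level]

    def __len__(self) -> int:
        return len(self.levels)


@dataclass
class OrientedPlane:
    """Square sampling plane: center, orthonormal frame (n, u, v), side D (µm)."""

    center: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray
    side_um: float
    pitch_um: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.side_um <= 0 or self.pitch_um <= 0:
            raise ValueError("plane side and pitch must be positive")
        basis = np.stack([self.normal, self.u, self.v])
        if not np.allclose(basis @ basis.T, np.eye(3), atol=1e-6):
            raise ValueError("plane basis {n, u, v} must be orthonormal")
        if np.dot(np.cross(self.u, self.v), self.normal) < 0:
            raise ValueError("plane basis must be right-handed (u x v = n)")

    @classmethod
    def from_normal(
        cls, center: np.ndarray, normal: np.ndarray, side_um: float, pitch_um: float
    ) -> "OrientedPlane":
        n, u, v = orthonormal_basis(normal)
        return cls(center, n, u, v, side_um, pitch_um)

    @property
    def side_px(self) -> int:
        return max(int(round(self.side_um / self.pitch_um)), 1)

    def pixel_to_world(self, rows, cols) -> np.ndarray:
        """Map plane pixel coordinates (row along u, col along v) to world µm."""
        half = (self.side_px - 1) / 2.0
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        off = (
            (rows - half)[..., None] * self.pitch_um * self.u
            + (cols - half)[..., None] * self.pitch_um * self.v
        )
        return self.center + off

    def world_to_pixel(self, world: np.ndarray) -> np.ndarray:
        half = (self.side_px - 1) / 2.0
        d = np.asarray(world, dtype=float) - self.center
        return np.array(
            [np.dot(d, self.u) / self.pitch_um + half, np.dot(d, self.v) / self.pitch_um + half]
        )

    def translated(self, offset_um: float) -> "OrientedPlane":
        return OrientedPlane(
            self.center + offset_um * self.normal,
            self.normal,
            self.u,
            self.v,
            self.side_um,
            self.pitch_um,
        )


@dataclass
class PlaneImage:
    """Resampled raster of an OrientedPlane, plus out-of-bounds pixel flags."""

    raster: np.ndarray
    plane: OrientedPlane
    oob: np.ndarray  # bool mask, True where the pixel fell outside the volume

    @property
    def pixel_pitch_um(self) -> float:
        return self.plane.pitch_um


def default_pitch(volume: VoxelGrid) -> float:
    """Native sampling pitch: the finest lateral spacing of the volume."""
    return float(min(volume.spacing[1], volume.spacing[2]))


def sample_plane(volume: VoxelGrid, plane: OrientedPlane) -> PlaneImage:
    """Trilinearly resample an oriented plane from the volume.

    Out-of-bounds pixels are set to 0 and flagged in ``oob``.
    """
    side = plane.side_px
    rows, cols = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    world = plane.pixel_to_world(rows, cols)  # (side, side, 3)
    idx = (world - volume.origin) / volume.spacing
    coords = np.moveaxis(idx, -1, 0)  # (3, side, side)
    raster = ndi.map_coordinates(
        volume.intensities.astype(np.float32, copy=False),
        coords,
        order=1,
        mode="constant",
        cval=0.0,
    )
    shape = np.asarray(volume.shape)
    oob = np.any((idx < 0) | (idx > shape - 1), axis=-1)
    raster[oob] = 0.0
    return PlaneImage(raster=raster, plane=plane, oob=oob)


def extract_local_slab(
    volume: VoxelGrid, plane: OrientedPlane, depth: int
) -> list[PlaneImage]:
    """Sample ``depth`` parallel planes starting at ``plane`` along +normal.

    Slice j is the target plane translated j * pitch along the normal; slice 0
    is the target plane itself.  All slices share the in-plane axes (u, v).
    """
    if depth < 1:
        raise ValueError("slab depth must be >= 1")
    return [sample_plane(volume, plane.translated(j * plane.pitch_um)) for j in range(depth)]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _downsample_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    shape = np.asarray(arr.shape)
    trimmed = (shape // factor) * factor
    a = arr[: trimmed[0], : trimmed[1], : trimmed[2]].astype(np.float32)
    a = a.reshape(
        trimmed[0] // factor, factor, trimmed[1] // factor, factor, trimmed[2] // factor, factor
    )
    return a.mean(axis=(1, 3, 5)).astype(arr.dtype if np.issubdtype(arr.dtype, np.floating) else np.float32)


def write_multiscale_zarr(
    volume: VoxelGrid,
    path: str | Path,
    n_levels: int = 3,
    factor: int = 2,
    chunks: tuple[int, int, int] = (64, 64, 64),
) -> None:
    """Write a volume as a chunked multiscale zarr group (OME-NGFF-style)."""
    import zarr

    root = zarr.open_group(str(path), mode="w")
    grp = root.create_group(volume.channel_id)
    data = volume.intensities
    datasets = []
    for level in range(n_levels):
        spacing = volume.spacing * (factor**level)
        arr = grp.create_array(
            str(level),
            shape=data.shape,
            dtype="float32",
            chunks=tuple(min(c, s) for c, s in zip(chunks, data.shape)),
        )
        arr[:] = data.astype(np.float32)
        datasets.append(
            {
                "path": str(level),
                "coordinateTransformations": [{"type": "scale", "scale": list(map(float, spacing))}],
            }
        )
        if level < n_levels - 1:
            data = _downsample_mean(data, factor)
    grp.attrs["multiscales"] = [
        {"version": "0.4", "axes": ["z", "y", "x"], "datasets": datasets, "factor": factor}
    ]
    grp.attrs["origin_um"] = list(map(float, volume.origin))


def write_tiff(volume: VoxelGrid, path: str | Path) -> None:
    import tifffile

    meta = {
        "spacing_um": list(map(float, volume.spacing)),
        "origin_um": list(map(float, volume.origin)),
        "channel_id": volume.channel_id,
    }
    tifffile.imwrite(str(path), volume.intensities.astype(np.float32), description=json.dumps(meta))


def write_hdf5(volume: VoxelGrid, path: str | Path) -> None:
    import h5py

    with h5py.File(str(path), "w") as f:
        ds = f.create_dataset(volume.channel_id, data=volume.intensities.astype(np.float32))
        ds.attrs["spacing_um"] = volume.spacing
        ds.attrs["origin_um"] = volume.origin


def load_volume(path: str | Path, level: int = 0, channel: str = "raw") -> VoxelGrid:
    """Load one resolution level of one channel from zarr/TIFF/HDF5.

    Spacing is scaled by the pyramid level's downsampling factor.
    """
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".zarr" or (p.is_dir() and (p / "zarr.json").exists()):
        return _load_zarr(p, level, channel)
    if suffix in (".tif", ".tiff"):
        return _load_tiff(p, level, channel)
    if suffix in (".h5", ".hdf5"):
        return _load_hdf5(p, level, channel)
    raise ValueError(f"unknown volume format: {p}")


def _load_zarr(path: Path, level: int, channel: str) -> VoxelGrid:
    import zarr

    root = zarr.open_group(str(path), mode="r")
    try:
        grp = root[channel]
    except KeyError:
        raise KeyError(f"channel {channel!r} not found in {path}") from None
    meta = grp.attrs["multiscales"][0]
    datasets = meta["datasets"]
    if level >= len(datasets):
        raise IndexError(f"level {level} not present (pyramid has {len(datasets)} levels)")
    entry = datasets[level]
    spacing = entry["coordinateTransformations"][0]["scale"]
    origin = grp.attrs.get("origin_um", [0.0, 0.0, 0.0])
    data = grp[entry["path"]][:]
    return VoxelGrid(data, spacing=spacing, origin=origin, channel_id=channel)


def _load_tiff(path: Path, level: int, channel: str) -> VoxelGrid:
    import tifffile

    if level != 0:
        raise IndexError("TIFF stacks are single-scale; only level 0 exists")
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    stored = meta.get("channel_id", "raw")
    if channel != stored:
        raise KeyError(f"channel {channel!r} not found (file holds {stored!r})")
    return VoxelGrid(
        data,
        spacing=meta.get("spacing_um", [1.0, 1.0, 1.0]),
        origin=meta.get("origin_um", [0.0, 0.0, 0.0]),
        channel_id=stored,
    )


def _load_hdf5(path: Path, level: int, channel: str) -> VoxelGrid:
    import h5py

    if level != 0:
        raise IndexError("HDF5 fixtures are single-scale; only level 0 exists")
    with h5py.File(str(path), "r") as f:
        if channel not in f:
            raise KeyError(f"channel {channel!r} not found in {path}")
        ds = f[channel]
        data = ds[:]
        spacing = ds.attrs.get("spacing_um", [1.0, 1.0, 1.0])
        origin = ds.attrs.get("origin_um", [0.0, 0.0, 0.0])
    return VoxelGrid(data, spacing=spacing, origin=origin, channel_id=channel)
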