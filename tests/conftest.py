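"""Shared phantom fixtures (session-scoped: volumes are reused across tests)."""

from __future__ import annotations

import numpy as np
import pytest

from tubetrace.phantom import (
    BranchSpec,
    NucleiSpec,
    PhantomSpec,
    WaveSpec,
    make_branching_phantom,
    make_tube_phantom,
    make_wave_phantom,
)
from tubetrace.segmentation import SegmentationModelSpec, mask_statistics
from tubetrace.tracking import TrackingConfig, track_tubule
from tubetrace.volume_io import OrientedPlane, sample_plane


@pytest.fixture(scope="session")
def default_model():
    return SegmentationModelSpec("default")


@pytest.fixture(scope="session")
def straight_mm_phantom():
    """1 mm straight wall-bright tube, r = 20 µm, 1 µm isotropic voxels."""
    spec = PhantomSpec(
        centerline_model={"kind": "line", "start": (35.0, 35.0, 30.0), "direction": (0, 0, 1), "length": 1000.0},
        radius_profile={"kind": "constant", "radius": 20.0},
        volume_shape=(70, 70, 1060),
        rng_seed=1,
    )
    grid, truth = make_tube_phantom(spec)
    seeds = (np.array([35.0, 35.0, 30.0]), np.array([35.0, 35.0, 38.0]))
    stop = [np.array([35.0, 35.0, 1030.0])]
    return grid, truth, seeds, stop


@pytest.fixture(scope="session")
def straight_track(straight_mm_phantom, default_model):
    grid, truth, seeds, stop = straight_mm_phantom
    track = track_tubule(grid, seeds, TrackingConfig(), default_model, stop_points=stop, track_id="mm")
    return track


@pytest.fixture(scope="session")
def step_phantom():
    """40 -> 16 µm diameter step at mid-length (thin-segment transition)."""
    spec = PhantomSpec(
        centerline_model={"kind": "line", "start": (35.0, 35.0, 25.0), "direction": (0, 0, 1), "length": 500.0},
        radius_profile={"kind": "steps", "steps": [(0.0, 20.0), (250.0, 8.0)]},
        volume_shape=(70, 70, 560),
        intensity_model={"kind": "wall_bright", "wall_thickness_um": 4.0},
        rng_seed=2,
    )
    grid, truth = make_tube_phantom(spec)
    seeds = (np.array([35.0, 35.0, 25.0]), np.array([35.0, 35.0, 32.0]))
    stop = [np.array([35.0, 35.0, 525.0])]
    return grid, truth, seeds, stop


@pytest.fixture(scope="session")
def kink_phantom():
    """Sharp 85-degree bend in a 40 µm tube (the rotational-search regime)."""
    r, L, turn = 20.0, 150.0, np.deg2rad(85.0)
    p0 = np.array([4 * r, 4 * r, 4 * r])
    p1 = p0 + np.array([0.0, 0.0, L])
    p2 = p1 + np.array([0.0, np.sin(turn), np.cos(turn)]) * L
    hi = np.maximum.reduce([p0, p1, p2]) + 4 * r
    spec = PhantomSpec(
        centerline_model={"kind": "piecewise_polyline", "points": [p0, p1, p2]},
        radius_profile={"kind": "constant", "radius": r},
        volume_shape=tuple(int(np.ceil(v)) for v in hi),
        rng_seed=3,
    )
    return make_tube_phantom(spec)


@pytest.fixture(scope="session")
def gap_phantom():
    """Straight tube with a 3-diameter stain gap (occlusion) at mid-length."""
    spec = PhantomSpec(
        centerline_model={"kind": "line", "start": (35.0, 35.0, 25.0), "direction": (0, 0, 1), "length": 500.0},
        radius_profile={"kind": "constant", "radius": 20.0},
        volume_shape=(70, 70, 560),
        gaps_um=[(230.0, 350.0)],
        rng_seed=4,
    )
    grid, truth = make_tube_phantom(spec)
    seeds = (np.array([35.0, 35.0, 25.0]), np.array([35.0, 35.0, 32.0]))
    stop = [np.array([35.0, 35.0, 525.0])]
    return grid, truth, seeds, stop


@pytest.fixture(scope="session")
def y_phantom():
    """Straight parent with one 45-degree branch (Y configuration)."""
    child = PhantomSpec(
        centerline_model={
            "kind": "line",
            "start": (0, 0, 0),
            "direction": (0, np.sin(np.pi / 4), np.cos(np.pi / 4)),
            "length": 160.0,
        },
        radius_profile={"kind": "constant", "radius": 14.0},
        volume_shape=(1, 1, 1),
    )
    spec = PhantomSpec(
        centerline_model={"kind": "line", "start": (60.0, 60.0, 40.0), "direction": (0, 0, 1), "length": 400.0},
        radius_profile={"kind": "constant", "radius": 20.0},
        volume_shape=(120, 240, 480),
        branch_specs=[BranchSpec(attach_arclength_um=200.0, child=child)],
        rng_seed=5,
    )
    return make_branching_phantom(spec)


@pytest.fixture(scope="session")
def reconnect_phantom():
    """Branch that leaves the parent at s=150 µm and rejoins it at s=450 µm."""
    s1, s2, amp = 150.0, 450.0, 80.0
    xs = np.linspace(0, s2 - s1, 40)
    pts = np.stack([np.zeros_like(xs), amp * np.sin(np.pi * xs / (s2 - s1)), xs], 1)
    child = PhantomSpec(
        centerline_model={"kind": "piecewise_polyline", "points": pts},
        radius_profile={"kind": "constant", "radius": 14.0},
        volume_shape=(1, 1, 1),
    )
    spec = PhantomSpec(
        centerline_model={"kind": "line", "start": (60.0, 60.0, 40.0), "direction": (0, 0, 1), "length": 600.0},
        radius_profile={"kind": "constant", "radius": 20.0},
        volume_shape=(120, 240, 680),
        branch_specs=[BranchSpec(attach_arclength_um=s1, child=child, reconnect_at_um=s2)],
        rng_seed=5,
    )
    return make_branching_phantom(spec)


@pytest.fixture(scope="session")
def nuclei_phantom():
    """2 mm tube with 50 in-lumen nuclei (0.5 per 20 µm window)."""
    spec = PhantomSpec(
        centerline_model={"kind": "line", "start": (40.0, 40.0, 30.0), "direction": (0, 0, 1), "length": 2000.0},
        radius_profile={"kind": "constant", "radius": 20.0},
        volume_shape=(40, 40, 1045),
        voxel_spacing=(2.0, 2.0, 2.0),
        nuclei_spec=NucleiSpec(linear_density_per_um=0.025, radius_um=5.0, in_lumen_fraction=1.0),
        rng_seed=11,
    )
    grid, truth = make_tube_phantom(spec)
    seeds = (np.array([40.0, 40.0, 30.0]), np.array([40.0, 40.0, 38.0]))
    stop = [np.array([40.0, 40.0, 2030.0])]
    return grid, truth, seeds, stop


@pytest.fixture(scope="session")
def four_tube_setup(tmp_path_factory):
    """Four parallel tubes in one volume, written as multiscale zarr + seeds."""
    from tubetrace.volume_io import VoxelGrid, write_multiscale_zarr

    ys = [40.0, 100.0, 160.0, 220.0]
    vols = []
    for i, y in enumerate(ys):
        spec = PhantomSpec(
            centerline_model={"kind": "line", "start": (40.0, y, 30.0), "direction": (0, 0, 1), "length": 300.0},
            radius_profile={"kind": "constant", "radius": 16.0},
            volume_shape=(40, 130, 190),
            voxel_spacing=(2.0, 2.0, 2.0),
            rng_seed=20 + i,
        )
        g, _ = make_tube_phantom(spec)
        vols.append(g.intensities)
    combined = VoxelGrid(np.maximum.reduce(vols), spacing=(2.0, 2.0, 2.0), channel_id="raw")
    path = tmp_path_factory.mktemp("fourtube") / "vol.zarr"
    write_multiscale_zarr(combined, path, n_levels=2)
    seeds = [
        {"id": f"t{i}", "seed1_zyx_um": [40, y, 30], "seed2_zyx_um": [40, y, 38], "stop_points": [[40, y, 330]]}
        for i, y in enumerate(ys)
    ]
    model = SegmentationModelSpec("default", diameter_prior_um=32.0)
    return str(path), seeds, model


WAVE_EXTENT_UM = 1200.0
WAVE_PATTERN = (
    [("dark", WAVE_EXTENT_UM), ("sparse_clusters", WAVE_EXTENT_UM), ("dense_clusters", WAVE_EXTENT_UM)] * 3
    + [("sparse_clusters", WAVE_EXTENT_UM), ("dark", WAVE_EXTENT_UM)]
)  # 3 forward periods then a reversed tail -> 3 waves + 1 reversal


@pytest.fixture(scope="session")
def wave_phantom():
    length = sum(e for _, e in WAVE_PATTERN)
    spec = PhantomSpec(
        centerline_model={"kind": "line", "start": (50.0, 50.0, 70.0), "direction": (0, 0, 1), "length": length},
        radius_profile={"kind": "constant", "radius": 30.0},
        volume_shape=(50, 50, int((length + 140) / 4) + 1),
        voxel_spacing=(2.0, 2.0, 4.0),
        intensity_model={"kind": "wall_bright", "wall_thickness_um": 8.0, "lumen": 40.0},
        contrast=6.0,
        background=10.0,
        noise_sd=4.0,
        wave_spec=WaveSpec(pattern=list(WAVE_PATTERN)),
        rng_seed=7,
    )
    return make_wave_phantom(spec)


@pytest.fixture(scope="session")
def wave_frames(wave_phantom):
    """Frames every 20 µm along the wave tube with truth disk masks + labels."""
    grid, truth = wave_phantom
    length = truth.centerline.length_um
    arcs = np.arange(10.0, length, 20.0)
    side_px = 75
    rr, cc = np.meshgrid(np.arange(side_px), np.arange(side_px), indexing="ij")
    disk = ((rr - side_px // 2) ** 2 + (cc - side_px // 2) ** 2) * 4.0 <= 30.0**2
    frames, masks, labels = [], [], []
    for s in arcs:
        plane = OrientedPlane.from_normal(np.array([50.0, 50.0, 70.0 + s]), (0, 0, 1), 150.0, 2.0)
        img = sample_plane(grid, plane)
        frames.append(img)
        masks.append(mask_statistics(disk, img))
        labels.append(truth.label_at(s))
    return arcs, frames, masks, labels
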