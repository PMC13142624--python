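# tubetrace

Semi-automated 3D tracking, reconstruction, and quantitative analysis of
tubular structures in volumetric microscopy.

Organ-scale cleared-tissue imaging produces volumes in which individual
renal tubules (nephrons) or seminiferous tubules wind for millimetres
through densely packed tissue.  Mapping one tubule means following its
centerline through thousands of image planes — prohibitive by hand, and
brittle for fully automatic segmentation because diameters change abruptly
(a proximal tubule at ~40 µm narrows to a ~16 µm thin limb), paths bend
sharply, and staining fails locally.  `tubetrace` is for microscopists and
image analysts who need complete single-tubule reconstructions from such
volumes with minimal human input.

## The method

Starting from a two-point seed, the tracker propagates the centerline by
**stepwise vector tracking**: at each step the forward direction comes from
the last two nodes, a plane orthogonal to it is sampled one step ahead,
segmented, and the node snaps to the centroid of the cross-section mask
under the plane center.  Runtime parameters adapt to the running-average
cross-section diameter d′ (clamped to [d_min, d_max]):

    S = round(d′ / k_step)      node step size          (k_step  = 5)
    J = round(d′ / k_jitter)    diameter sweep jitter   (k_jitter = 3)
    D = round(d′ · k_dim)       plane side length       (k_dim  = 2.5)

Two further recovery modules fire only when needed.  **Rotational search**:
when a cross-section is highly elongated (eccentricity ≥ 0.75), the plane is
rotated about the ellipse minor axis r = −sin φ·u + cos φ·v over −60°…+60°
in 10° steps and the roundest candidate's normal becomes the new forward
direction.  **Troubleshooting / model switching**: when no mask is found, a
10-slice local slab is segmented under the diameter sweep {d′, d′−J, d′+J}
(stage 1: current model; stage 2: the whole model suite), the hypotheses are
fused by majority vote with a depth-persistence rule, and the model/diameter
whose hypothesis best matches the consensus (highest IoU) is adopted.
Tracks that exhaust recovery enter a file-based correction queue; one or two
clicked points resume them.

Downstream, cross-sections are interpolated into voxel-level 3D
reconstructions, straightened into uniform arc-length stacks (longitudinal
cut-through views), profiled for diameter, curvature κ and torsion τ,
populated with nuclei counts per 20 µm window (linear and volumetric
densities), and — for seminiferous tubules — staged frame-by-frame into the
dark / sparse-clusters / dense-clusters classes of the spermatogenic wave
with a four-parameter hierarchical intensity classifier (a, b, c, d),
smoothed along the tubule with a 2 mm modal window, and counted into
complete waves and reversals.

A phantom module generates synthetic tubular volumes (lines, arcs, helices,
sharp bends, diameter steps, branches with reconnections, stain gaps,
planted nuclei, wave patterns) with complete ground truth; every quantitative
claim in the test suite is checked against planted truth.  See
`docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
import numpy as np
from tubetrace.phantom import PhantomSpec, make_tube_phantom
from tubetrace.tracking import TrackingConfig, track_tubule
from tubetrace.segmentation import SegmentationModelSpec
from tubetrace.reconstruct import interpolate_cross_sections
from tubetrace.morphometry import mask_metrics

# 1 mm wall-bright tube, radius 20 um, 1 um isotropic voxels
spec = PhantomSpec(
    centerline_model={"kind": "line", "start": (35.0, 35.0, 30.0),
                      "direction": (0, 0, 1), "length": 1000.0},
    radius_profile={"kind": "constant", "radius": 20.0},
    volume_shape=(70, 70, 1060),
    rng_seed=1,
)
volume, truth = make_tube_phantom(spec)

track = track_tubule(
    volume,
    seeds=(np.array([35.0, 35.0, 30.0]), np.array([35.0, 35.0, 38.0])),
    config=TrackingConfig(),
    models=SegmentationModelSpec("default"),
    stop_points=[np.array([35.0, 35.0, 1030.0])],
)
print(f"status={track.status}  nodes={len(track.nodes)}  "
      f"tracked length={track.length_um:.0f} um")

diam = np.mean([n.diameter_um for n in track.nodes])
dev = np.linalg.norm(track.points[:, :2] - 35.0, axis=1).mean()
print(f"mean diameter = {diam:.1f} um (planted: 40.0)")
print(f"mean centerline deviation = {dev:.2f} um")

rec = interpolate_cross_sections(track, volume)
iou = mask_metrics(rec.full(volume.shape), truth.mask)["iou"]
print(f"reconstruction IoU vs ground truth = {iou:.3f}")
```

Output:

```
status=complete  nodes=124  tracked length=988 um
mean diameter = 40.0 um (planted: 40.0)
mean centerline deviation = 0.23 um
reconstruction IoU vs ground truth = 0.931
```

The track walks the full millimetre in 124 adaptive steps (S = 8 µm at
d′ = 40 µm) without any human intervention; the recovered diameter matches
the planted tube, the centerline stays within a quarter-voxel of the true
axis on average, and the voxelized reconstruction overlaps the ground-truth
tube at IoU 0.93 (the residual is the half-voxel ambiguity of the wall edge
plus the final ~10 µm before the declared stop point).

Morphometry on an analytic helix (R = 50 µm, c = 25 µm) recovers the
closed-form κ = R/(R²+c²) and τ = c/(R²+c²):

```
helix curvature = 0.01600 /um (analytic 0.01600)
helix |torsion| = 0.00800 /um (analytic 0.00800)
```

## Command line

`tubetrace` exposes subcommands `phantom`, `track`, `straighten`, `profile`,
`cytometry`, `wavestage`, and `evaluate`; `track` reads a JSON-lines seeds
file, writes per-track centerlines/reconstructions/profiles, appends
unresolved tracks to `flags.jsonl`, and on re-run resumes any flagged track
that has an entry in `corrections.jsonl`:

```bash
tubetrace phantom --out demo --kind straight --length 500 --radius 20
tubetrace track --volume demo.zarr --channel raw --seeds seeds.jsonl --out run/ --workers 4
```

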