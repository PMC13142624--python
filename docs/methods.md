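# Methods

`tubetrace` reconstructs tubular structures (renal tubules, seminiferous
tubules) from 3D microscopy volumes by stepwise vector tracking of the
centerline with orthogonal cross-section segmentation, and derives voxel
reconstructions, straightened views, morphometric profiles, nucleus
densities, and cross-section stage sequences from the result.  This note
records the model, its assumptions, the parameters that matter, and the
design choices made where the method left them open.

## Coordinates and units

All world coordinates are (z, y, x) in micrometres, 0-based, with
`world = voxel index × spacing`.  This matches the axis order of chunked
microscopy formats (zarr, TIFF stacks, HDF5).  All physical quantities —
lengths, diameters, curvature (1/µm), densities — are in µm-derived units.

## The tracking loop

Tracking starts from a two-point seed: the initial forward direction is the
normalized difference of the seeds.  Each iteration:

1. derives runtime parameters from the running-average cross-section
   diameter d′ (mean of the last W = 10 accepted diameters, clamped to
   [d_min, d_max] = [0.8, 50] µm; initialized at 34 µm):
   step `S = round(d′/k_step)`, diameter jitter `J = round(d′/k_jitter)`,
   plane side `D = round(d′·k_dim)`, with `k_step = 5`, `k_jitter = 3`,
   `k_dim = 2.5`.  S and J are floored at 1 µm and D at 3 pixels so the loop
   cannot stall at the lower diameter clamp;
2. proposes the next node at `last + S·forward`, samples a square plane of
   side D orthogonal to `forward` (trilinear interpolation at the volume's
   native lateral pitch; out-of-bounds pixels are zero and excluded from
   thresholding), segments it, and selects the mask overlapping the plane
   center;
3. repositions the node to the mask centroid and sets
   `forward = normalize(new − previous)`.  In-plane axes (u, v) are carried
   by rotation-minimizing transport so the ellipse orientation φ is stable
   from step to step.

Termination: arrival within tolerance of a declared stop point (complete),
the proposal leaving the volume (terminated_boundary), proximity to an
already-reconstructed centerline (terminated_merge), a stall (backtracking
within 0.25·S of a node more than 3 steps old, or a direction reversal with
dot < −0.5), or exhaustion of the recovery cascade (flagged for manual
correction).  A correction appends one or more manual nodes and returns the
track to the queue; tracking resumes from the last two nodes.

### Mask acceptance and the diameter band

The built-in segmentation backends are classical: Otsu threshold → hole
filling → removal of objects smaller than (0.25·diameter_prior)² in area →
labeling (`builtin-threshold`; `builtin-lumen` is the same on the inverted
image).  Because hole filling closes the dim lumen inside a bright wall,
wall-bright tubules segment to their full disk.

On top of the backend, the tracker accepts a center mask only when its
equivalent circular diameter lies within a multiplicative band of the
current prior: `d ∈ [d′/f, f·d′]` with `f = diameter_band = 2`.  This gate
emulates the scale sensitivity of learned segmenters whose diameter
parameter determines what they detect, and it is what gives model switching
its meaning: a mask that is far from the expected scale is treated as a
segmentation failure and routed to the troubleshooting module, which can
adopt a different diameter (and model).  Without a scale gate a pure
threshold backend is diameter-agnostic and the diameter sweep would be
inert.

### Rotational search (RS)

Triggered when the selected mask's second-moment ellipse has eccentricity
≥ 0.75.  The plane is rotated about the ellipse's minor axis
`r = −sin φ·u + cos φ·v` from −60° to +60° in 10° steps (13 candidates,
including 0°); each candidate is re-segmented, the lowest-eccentricity
candidate wins (ties toward the smallest |angle|), its mask becomes the
cross-section and its normal the new forward direction.

The trigger default of 0.75 (axis ratio 1.5:1, ≈ 49° of obliquity)
was set by measuring tracking dynamics on sharp-bend phantoms: cross-section
eccentricity reaches only ≈ 0.75–0.88 before a track is lost at a sharp
bend, so a higher trigger (e.g. 0.9) leaves the module unable to fire before
failure.  A relevant empirical finding: on *smooth* bends the centroid
repositioning step self-corrects plane orientation — the per-step turn is
S/R_bend ≈ 4° whenever the bend radius is a small multiple of the tube
diameter, because S scales with the diameter too — so RS contributes only at
near-discontinuous bends, consistent with its role as the smallest of the
three recovery modules.  The module's effective operating window is bends
turning roughly 80–90° within a step or two: gentler turns are absorbed by
centroid repositioning alone, while turns well beyond the ±60° sweep exceed
what any candidate plane can reach.  The validation bend phantom uses an
85° turn, squarely inside that window.

### Troubleshooting and model switching (TS)

Invoked when no acceptable center mask exists.  Stage 1 applies the current
model to a local slab (10 slices deep, target plane first, slices spaced one
pixel pitch along the normal, sharing the target plane's in-plane axes)
under a diameter sweep {d′, d′−J, d′+J}.  The hypothesis segmentations are
fused by per-pixel majority vote; hypotheses whose slab contains no
foreground anywhere abstain (a sweep exists precisely because some priors
find nothing — counting empty slabs as "no" votes would veto every genuine
recovery at a diameter transition, since a diameter at which the incumbent
prior fails can be in-band for at most the adjacent sweep values).  The
consensus is restricted to the 26-connected 3D component containing the
target-plane center, which must persist over at least half the slab depth.
If stage 1 yields a center mask the tracker adopts it, and adopts the
equivalent diameter of the highest-IoU hypothesis into the running average;
stage 2 repeats the sweep across the whole model suite and adopts the model
of the highest-IoU hypothesis (ties toward the incumbent model, then the
larger IoU union).  If both stages fail the track is flagged with one queue
entry — every segmentation failure ends in exactly one of {recovery,
flag}.

### Merging and branch points

Finished tracks are merged longest-first.  Nodes within `tolerance` (10 µm
default) of an already-kept centerline are trimmed (a fully-overlapping
track is absorbed); a junction is recorded at each attachment.  Because two
tubules' cross-sections fuse before their centerlines touch, a track also
terminates in `terminated_merge` when its proposal comes within
max(tolerance, 1.25·d′) of an existing centerline, and an endpoint within
`tolerance + local diameter` of another centerline is attached as a
junction.  Junction degree counts incident segments (a host passed through
contributes 2); degree ≥ 3 is a branch point, except that when a guest
segment attaches to the same host at both ends — it rejoins its own
tubule's path — the downstream attachment is classified as a reconnection
and not counted as an additional branch.

## Reconstruction and straightening

Each node's mask is encoded as a radial contour r(θ) about its centroid
(64 spokes, walked at half-pixel steps; approximately star-convex
cross-sections assumed, which holds for tubule lumina).  Centroids and
radial functions are linearly interpolated between consecutive nodes at arc
steps of half the minimum voxel spacing, and each interpolated polygon is
rasterized (polygon fill at native pitch) and stamped into the voxel grid.
Straightened stacks resample orthogonal planes at a uniform arc interval
with rotation-minimizing frames; the longitudinal cut-through view takes the
central row of each frame by default (max projection available).

## Morphometry

The centerline is resampled uniformly (default step: median node spacing)
and optionally pre-smoothed with a short moving average to suppress
segmentation jitter.  Curvature is the inverse circumradius of consecutive
point triples; torsion is the signed dihedral angle between consecutive
osculating planes divided by the arc step.  On analytic curves both
estimators converge monotonically with the step (verified on circle R = 100 µm:
κ = 0.01/µm, and helix R = 50, c = 25 µm: κ = R/(R²+c²) = 0.016/µm,
|τ| = c/(R²+c²) = 0.008/µm, each within 5 % at 5 µm steps).
Loop-type classification uses the thin-limb length rule (< 1.4 mm → short
loop) and/or inner-medulla entry from a four-region atlas (cortex, OSOM,
ISOM, IM); segment annotations are user-supplied intervals.

Tracking evaluation counts breaks against a ground-truth centerline: a break
is the first node deviating more than 2× the local truth diameter (a
scale-aware reading of "excessive deviation"), a stall, or a segmentation
failure; tracking restarts from the nearest truth point and the
uninterrupted lengths are accumulated.

## Cytometry

Nuclei are detected in the DNA channel by Gaussian smoothing, Otsu
thresholding, and watershed splitting on the distance transform (one
centroid per object, minimum separation set by the expected nucleus
radius); a learned 3D segmenter can be substituted through the backend
argument.  A nucleus is assigned to a tubule when its centroid voxel is
foreground in the tubule's voxel reconstruction (equivalent, at native
resolution, to a mesh-interior test, without meshing).  Densities use
consecutive 20 µm windows along the centerline: linear density is
count/window; volumetric density divides by the reconstruction volume whose
voxels are nearest to that window (reported missing where that volume is
zero); segment values are means across the segment's windows.

## Wave staging

Cross-section frames are classified hierarchically with four parameters:
threshold-1 is `a ×` the median intensity inside the mask (`a` is a
dimensionless multiplier because a value like 2.5 cannot be a raw intensity;
a raw-intensity variant is switchable); a frame is **dark** when the bright
fraction of the mask area is below `b`.  Otherwise the frame is
re-thresholded at the raw intensity `c` and 8-connected components are
extracted: **sparse clusters** when the two largest components hold less
than fraction `d` of the total bright area, else **dense clusters**.  A
frame with no pixels above `c` is dark by convention.  Labels are smoothed
with a rolling modal window (2 mm default; ties keep the previous label).
Runs of equal labels are traversed in the cyclic order dark → sparse →
dense → dark; a complete wave is three consecutive runs covering all three
classes in one direction (counted greedily, non-overlapping), and a
reversal is a sign change between adjacent run transitions.  Calibration is
an exhaustive grid search maximizing macro-F1 (ties toward smaller `a`,
then smaller `c`), with per-frame features cached per threshold so the cost
scales with the threshold grids rather than the full product.

## The phantom generator

Phantoms emulate cleared-tissue staining regimes: bright tubule walls
(contrast × background, default 5 × 20 intensity units) around a dim lumen,
additive Gaussian noise (σ = 5) clipped at zero, abrupt diameter steps
(40 → 16 µm), sharp bends, branches with optional reconnection, planted
stain gaps (occlusions), in-lumen nuclei, and periodic wave patterns
(sparse = many thin bright rods in the wall, dense = two thick bright rods
at the rim, dark = none; object intensity 150 over a 60/40/10
wall/lumen/background profile so that the canonical thresholds a = 2.5,
b = 0.02, c = 86, d = 0.62 separate the classes).  Walls are rendered from
the distance of each voxel to a dense centerline resampling (step ≤ ¼
voxel); at junctions the render is the union over tubes with lumen taking
precedence over wall, so fused lumens connect while the outer wall stays
closed.  Planted nuclei are rejection-sampled to at least one diameter of
separation so that a correct detector can resolve every one of them.

What the phantoms do **not** model: optical PSF and anisotropic blur, tile
seams and striping, clearing artifacts, intensity falloff with depth,
non-uniform staining within a class, and crowding by neighbouring tubules.
Passing the phantom suite therefore demonstrates the correctness of the
geometry, recovery logic, and bookkeeping — not segmentation robustness on
real stained tissue, where learned per-segment models plugged into the
backend registry carry that burden.

## Problem sizes and numerical choices

Validation runs use desk-scale volumes chosen to exercise every code path:
a 1 mm straight tube at 1 µm isotropic voxels (tracking accuracy,
reconstruction IoU ≥ 0.85), a 500 µm tube with a 40→16 µm step
(troubleshooting), an 80° sharp bend in a 40 µm tube (rotational search), a
2 mm tube with 50 nuclei (cytometry), a 13.2 mm straight tube with
1.2 mm class extents (wave staging against the 2 mm smoothing window), and
four parallel 300 µm tubes (parallel equivalence).  Ellipse fits regularize
second moments by one-twelfth of the squared pixel pitch (the variance of a
uniform pixel) so single-row masks stay finite; degenerate (collinear)
masks raise.  Consensus voting on an even number of voters requires ≥ half.
All randomness flows through explicit integer seeds; identical volume,
configuration and seeds reproduce tracks bit-identically, and per-track
work shares no mutable state, so worker count cannot change results.

## Known limitations

- The radial-contour interpolation falls back to effectively nearest-node
  shapes for strongly non-convex cross-sections.
- The diameter band treats genuine two-fold diameter jumps within a single
  step as failures first and recoveries second; a jump beyond `f²` within
  one step (e.g. 5×) is not recoverable by the ±J sweep alone and ends in a
  flag — which is the designed behaviour, not an error path.
- Junction positions inherit the attachment geometry: a branch meeting at a
  shallow angle registers its junction up to about one tube diameter away
  from the true centerline intersection.
- `evaluate_tracking` restarts slightly past the point of deviation, so the
  sum of uninterrupted lengths can undercount the truth length by a few
  diameters per break.
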