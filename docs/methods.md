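# Methods

## The selection problem

Given a host who needs a structural allograft (here: distal femur) and a
bank of CT-scanned donor bones, pick the donor whose outer surface best
matches the geometry the host needs. The host's own affected bone is
usually tumor-distorted and incomplete, so the intact contralateral bone,
reflected across the sagittal plane, serves as the geometric target (the
*mirror model*). Selection is two-staged: a cheap size screen in landmark
space, then full surface matching of the few survivors.

## Synthetic anatomy

The generator builds a distal-femur-like implicit solid as the smooth union
(soft-min with 2 mm blending length) of

- a *medial condyle* ellipsoid centered at (A/4, 0, 0) with semi-axes
  (A/4, B/2, 0.40·B),
- a *lateral condyle* ellipsoid centered at (−A/4, 0, 0) with semi-axes
  (A/4, C/2, 0.40·C),
- a *shaft* cylinder of the given radius and length, offset slightly
  medially (0.06·A) and posteriorly (0.08·B) so the shape is genuinely
  chiral even when B = C,

sampled on a regular grid (default pitch 1.5 mm) and meshed with marching
cubes. The synthetic frame is fixed: x = medial-lateral with the sagittal
plane at x = 0, y = anterior-posterior, z = proximal-distal.

Ground-truth landmarks sit at the analytic ellipsoid extremes — ME/LE at
(±A/2, 0, 0), MA/MP at (A/4, ±B/2, 0), LA/LP at (−A/4, ±C/2, 0) — so the
ABC measures of a noise-free bone reproduce the generative parameters
*exactly*, which is the round-trip invariant every downstream test leans
on. A left-side bone is the exact reflection of the canonical right-side
bone (winding reversed), making chirality identities hold to machine
precision.

Surface noise displaces each vertex along its outward normal by
N(0, σ); each landmark inherits the displacement of its nearest surface
vertex. Because landmark normals are nearly collinear with the measurement
axes, a landmark-pair distance then fluctuates ≈ N(0, √2·σ) — the measured
100-seed spread (97% of ABC deviations within 3σ, none beyond 5σ at
σ = 0.3 mm) matches this and is what the tests assert.

Tumor-like defects remove all vertices inside a sphere (with ±10% seeded
per-vertex radius jitter for an irregular rim) and leave the boundary open,
emulating incomplete tumoral models; a defect that would erase the whole
mesh is an error.

Default study conditions (chosen once as clinically plausible for an adult
distal femur and used throughout the tests): A, B, C ~ N((80, 60, 62),
(4, 3, 3)) mm, shaft length 100 mm, shaft radius 0.19·A, surface noise
0.2 mm when noise is wanted, CT rasterization at 0.5 mm isotropic voxels
with bone 1000 / background 0 intensity.

## Rasterization (emulated CT)

Voxel centers (0-based indices; center of voxel (i,j,k) at origin +
index·spacing) are classified inside/outside a closed mesh by parity of
surface crossings along +z rays through each voxel column. Ray origins
carry a ~10⁻⁶·spacing lateral offset so rays never pass exactly through
mesh edges; triangles perpendicular to the image plane contribute no
transversal crossing and are skipped. The grid covers the mesh with ≥ 2
voxels of margin. On an r = 20 mm sphere at 0.5 mm spacing the recovered
voxel volume is within 0.3% of 4/3·π·r³.

## Segmentation and reconstruction

Dual-threshold classification (default low = 300 HU-equivalent, high = ∞,
the cortical-bone convention) → largest connected component
(26-connectivity default; exact ties broken toward the component containing
the smallest flattened voxel index) → marching cubes at iso 0.5 on the
binary mask (optional Gaussian pre-smoothing, off by default), with
vertices mapped to mm by index·spacing + origin and winding oriented
outward via the signed-volume sign. Interactive mask editing, as done in
commercial segmentation suites, is deliberately out of scope; fidelity is
defined against the synthetic generating mesh (sub-voxel mean deviation at
0.5 mm spacing), not against any particular commercial tool's output.

## Distances and registration

**Exact point-to-surface queries.** Surface comparison between
independently tessellated meshes needs point-to-*triangle* (not vertex)
distances. For each query point the nearest-vertex distance is an upper
bound d; any triangle closer than d must have its centroid within
d + r_max (r_max = the largest centroid-to-corner radius in the mesh), so a
KD-tree ball query over centroids yields a candidate set that provably
contains the minimizer. Candidates are resolved with the standard
Voronoi-region closest-point-on-triangle case analysis (with an
edge-fallback for zero-area slivers). Results equal an exhaustive scan to
float precision.

**Landmark alignment** is closed-form least squares over the six named
pairs (SVD/Kabsch, reflection branch forced to det = +1, no scaling);
near-collinear configurations raise a degeneracy error.

**Trimmed ICP.** Iterate: exact nearest surface point for every
transformed source point → drop the worst `trim_fraction` (default 0.1;
0.2 recommended for heavily incomplete hosts) → closed-form rigid re-fit on
the retained pairs. Because the re-fit minimizes the retained SSD and
re-matching can only shorten each point's distance, the trimmed mean is
non-increasing across iterations (asserted in tests). Convergence: change
in trimmed mean < 1e-4 mm (default) or 100 iterations. The source is the
host-mirror cloud (the smaller/partial object), the target the donor mesh;
the seed only controls source subsampling (default 5000 points). Scaling is
never estimated — allograft selection compares true sizes — and
`RigidTransform` rejects det = −1 matrices, so registration cannot flip
chirality.

**Landmark-free initialization** (diaphyseal/transepiphyseal segments)
aligns centroids and principal axes; the 4-fold proper-rotation sign
ambiguity is resolved by evaluating the post-alignment mean surface
distance of each candidate. Adjacent principal-moment ratios below 1.01 (a
sphere-like object) trigger an ambiguity warning and a centroid-only
fallback.

## Scoring and ranking

The goodness-of-match is the mean of unsigned host→donor surface distances
over an area-uniform sample of the host mirror surface; RMS, one-sided
Hausdorff max and linearly interpolated 95th percentile are reported but do
not affect the default ordering. Distances run host→donor only because the
incomplete host makes donor→host distances misleading (the donor regions
"uncovered" by the defect would dominate); a symmetric variant can be
assembled from two calls. The colorimetric export clamps distances to a
fixed scale (default 0–5 mm, `coolwarm`) and writes uint8 vertex-color PLY
plus a JSON legend.

ABC screening uses weighted Euclidean distance in (A, B, C) space (unit
weights by default; a max-absolute-delta metric is available for
per-measure tolerance thinking), forwards the nearest k = 5 donors of the
same chirality as the resected side (a flag allows contralateral donors),
and breaks exact ties lexicographically by donor id so rankings are fully
deterministic.

## Problem sizes used in tests and the acceptance script

Meshes at 1.5 mm implicit-grid pitch (≈28k faces) where geometric accuracy
is measured, 2.0–2.5 mm for volume/ranking trials; ICP clouds of 1000–5000
points; reconstruction fidelity at the canonical 0.5 mm voxel pitch;
screening oracle over 500–1000 random banks of ≤ 50 donors; planted-twin
selection over 100 seeded trials (10-donor banks, 0.2 mm surface noise) in
the test suite and 30 trials in the acceptance script. These sizes were
chosen so each property is measured where it is informative while single-CPU
runs stay comfortable.

## Known limitations

- The synthetic femur is a geometric stand-in: no trabecular structure, no
  cartilage, no cortical-thickness variation, no realistic HU histogram
  (two intensity levels + Gaussian noise). Passing tests demonstrate the
  pipeline's geometric correctness and robustness to noise/partiality, not
  performance on clinical CT artifacts (beam hardening, metal, motion).
- Landmarks are operator inputs; no automatic landmark detection, so ABC
  reproducibility in practice is bounded by annotation repeatability.
- Segmentation is global dual-thresholding; low-calcium tumoral bone that
  falls below threshold simply becomes part of the "incomplete" host model,
  which the trimmed registration is designed to tolerate.
- Registration is rigid and local: initialization must be within the ICP
  basin (landmarks, or principal axes for elongated segments). No global
  feature-based registration.
- The sagittal mirror plane is user-supplied; no automatic symmetry-plane
  estimation.
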