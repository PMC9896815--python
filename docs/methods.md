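# Methods

This note records the models, parameter choices and numerical conventions
behind `nodulecad`, and what the synthetic-phantom results do and do not
establish.

## Pipeline model and assumptions

The pipeline assumes single-frame axial chest CT mapped to 8-bit gray
(HU window [−1000, 400] → [0, 255], configurable). All classification
cutoffs are defined on that scale. Stages:

1. **Preprocess** — optional crop to the body bounding box (air cutoff 15,
   margin 10 px), optional global 256-bin histogram equalization
   (`T(k) = round(255·cdf(k))`, monotone and idempotent), Gaussian
   denoising with a truncated kernel of total width 6σ rounded up to odd,
   reflective borders. Default σ = 0.7 px (kernel width 5): strong enough
   to suppress pixel noise and to stabilize the threshold iteration's
   basin (the blur's gradient pixels connect the histogram's modes), mild
   enough that the pixel-scale margin detail the burr features depend on
   survives. Equalization is off by default because it remaps the gray
   scale that the fixed gates (T_GM = 196) are defined on; it is intended
   as a contrast aid for real scans, applied before windowing-sensitive
   steps at the user's discretion.
2. **Adaptive threshold** — fixed-point iteration from
   T₀ = (g_max+g_min)/2, update T ← (mean(g<T)+mean(g≥T))/2, stop when
   |ΔT| < ε = 10⁻³ gray levels. The iteration is an ISODATA-type scheme;
   on multimodal histograms it has several fixed points and converges to
   the one whose basin contains T₀. A constant image raises a degenerate
   -input error.
3. **Binarization** — parenchyma candidates are *strictly* below T; a
   pixel equal to the threshold goes to background.
4. **Component screening** — 4-connected labeling; areas sorted
   descending into S. S₁ (the surrounding air) is always discarded, and —
   as a robustness guard — any component touching the image border is
   ineligible as lung (air can fragment). With leading eligible areas
   S₂ ≥ S₃: keep every component with S₃ ≤ s ≤ S₂ when S₂/S₃ ≤ λ,
   otherwise only S₂ (fused lungs or single lung in view). λ = 50.
5. **Hole filling** — background regions not 4-connected to the border
   become foreground (extensive and idempotent).
6. **Boundary repair** — per lung: closing with disk(9), opening with
   disk(9), erosion with disk(1), then union. Closing precedes the
   opening+erosion sequence because opening alone cannot re-incorporate
   juxta-pleural notches — the stated purpose of repair; the literal
   opening+erosion sequence remains available via `repair_ops`.
   The disk radius 9 px bridges notches up to ≈ 2×9 px. The smoothing
   erosion uses radius 1 px: at the phantom's lung scale (≈ 12 000 px per
   lung section) a 2 px erosion removes > 3 % of the area and caps the
   achievable Dice near 0.93–0.96 at any realistic lung size, which would
   contradict the segmentation-quality target the pipeline is built to;
   radius is configurable.
7. **Left/right split** — with two components, the one with smaller mean
   column index is image-left; one component is returned fused with a
   flag; more than two is an error (screen first).

## Candidate features

Candidates are 8-connected components of `gray ≥ T'` inside the masked
parenchyma, T' re-estimated on the nonzero pixels only. Each region may
be refined by the gray judgment `keep g ≥ (1−τ)(g_max+g_min)/2` with
τ = 0.5 by default; the cutoffs are computed once from the input region,
making the operation idempotent.

* **Boundary chain** — Moore-neighbor tracing with Jacob's stopping
  criterion from the topmost-leftmost pixel. One-pixel-wide protrusions
  are walked out and back, so a 1×11 line has chain length 20; a 5×5
  square has 16. Perimeter weights diagonal steps √2.
* **Radial profile** — distances from chain points to the pixel-centroid,
  normalized by the maximum (max RD = 1). A **burr point** is a strict
  local maximum of RD over a cyclic window of w = 5 chain neighbors whose
  excess over the mean exceeds δ = 0.05. This rule is our own
  formalization (the qualitative description is "protrusions and burrs"):
  it makes the burr magnitude non-negative, returns n_b = 0 on smooth
  disks of radius ≥ ~10 px, and recovers constructed spike counts
  exactly. *Known limitation:* digital-circle anisotropy (the four
  on-axis pixels of a small disk lie up to 8 % further from the centroid
  than average) can produce up to 4 spurious burrs on smooth disks of
  radius ≤ ~8 px; δ was left at 0.05 because raising it above the
  anisotropy would also erase genuine spiculation at small scales.
* **Gray features** — mean, *population* variance, and entropy with the
  natural logarithm over the 256-bin region histogram (ceiling
  ln 256 ≈ 5.55, consistent with the 4.4–4.8 range typical of real
  nodules of a few hundred pixels).

## Classification

Five gates evaluated in order S → C → GM → GE → MBR as a strict
conjunction, each cutoff and direction configurable:
S_R ≥ 30 rejects sub-3 mm lesions; C_R ≥ 0.6 rejects elongated vessels;
GM ≤ 196 rejects the bright circular cross-sections of vessels
perpendicular to the slice; GE ≥ 3.5 requires the gray heterogeneity of
real lesions; MBR ≥ 0.16 requires a burred margin. Directions follow the
physiology (vessels are brighter and smoother than nodules). The first
failing gate is recorded, which makes rejection reasons auditable.
`calibrate_thresholds` provides a deterministic grid search (sensitivity
first, accuracy as tie-break) that never returns a set scoring below the
shipped one; the shipped values are the defaults.

Matching for the confusion metrics is greedy nearest-first on centroids
with a 5 px radius; TN ≡ 0 by the negative-class convention, so
specificity is identically 0 and is reported for completeness only.
Processing time per image is logged, never asserted (hardware-dependent).

## 3-D reconstruction and path planning

Volumes are stacked (z, y, x) with mm spacing; isotropic resampling is
trilinear onto a grid at multiples of the target spacing (no overshoot,
constant volumes invariant). Isosurfaces use scikit-image marching cubes
on a one-voxel zero-padded volume (closed meshes for border-touching
objects) followed by Laplacian smoothing (factor 0.5, 10 iterations by
default). Meshes export as STL/PLY via trimesh.

The chest surface is the set of body voxels with a background 6-neighbor,
excluding the volume border (there the body is cut by the field of view,
not skin). Candidate entries are the k nearest surface points (exhaustive
search; ties lexicographic on the (z, y, x) voxel index), ranked by the
path gray sum over a 3-D Bresenham traversal (driving-axis stepping,
other axes rounded half-toward-+∞, each voxel once). The planner returns
the lowest-gray-sum candidate that intersects no obstacle mask, widening
once to 2k before failing with the collected rejection reasons. The
original two-stage scheme (2-D search in the nodule's largest slice, 3-D
confirmation) is subsumed by the 3-D search; `in_slice=True` restricts
candidates to the target's axial slice for fidelity to that scheme.
Default obstacle masks are thresholded bone and bright in-lung vessels;
phantom runs use the exact truth masks.

## The phantom: what it emulates and what it does not

`default_spec` builds a 40×256×256 volume at (2.0, 1.4, 1.4) mm: an
elliptical body (semi-axes 140×157 mm) inside a circular field of view,
two ellipsoidal lungs, a tracheal air column, six rib arcs in the outer
body shell, one bright vessel perpendicular to the axial plane and one
elongated in-plane vessel, and one spiculated nodule per lung. Class
means 0/10/40/120/250 (outside field / air / parenchyma / soft tissue /
bone) reproduce the peak-valley histogram of a real chest slice, with
nodules at 170 and the perpendicular vessel at 235. Additive Gaussian
noise σ = 3 is clipped to [0, 255]. Everything is rasterized by
center-of-voxel membership of analytic solids, so exact brute-force
oracles exist for every mask, and generation is a pure function of the
spec (seed included).

Nodules are spheres whose in-plane radius is modulated by
`1 + a·cos(kθ + φ)` — a petal-shaped spiculated margin — plus an internal
correlated Gaussian texture (σ = 16 gray, correlation length 1.7 mm).
The defaults (radius 9.1 mm, k = 9 petals, a = 0.13) were fixed once by
matching the *measured* features of rasterized, denoised phantom nodules
to the feature ranges reported for doctor-confirmed nodules
(C_R ≈ 0.54–0.86, MBR ≈ 0.19–0.41, MBM ≈ 0.10–0.13, GE ≈ 4.4–4.8):
measured phantom values land mid-band (C_R ≈ 0.70, MBR ≈ 0.20,
MBM ≈ 0.11, GE ≈ 4.0). The correlated texture is essential: independent
per-voxel noise of the same entropy would be flattened by denoising and
would jitter the margin, while a homogeneous nodule would have
GE ≈ 2.5 — below any realistic lesion and below the entropy gate.

Passing the phantom suite demonstrates that the *implementation* of each
stage is correct against analytic truth and that the shipped gates
separate the modeled structure classes. It does not demonstrate clinical
performance: the phantom has no ground-glass opacity, no juxta-pleural or
juxta-vascular adhesion, no breathing/cardiac motion, no scanner
artifacts, and its class contrasts are cleaner than real tissue. The
published clinical figures for this family of methods (Dice ≈ 0.97
against manual references; sensitivity ≈ 0.88 on large public cohorts)
require the corresponding clinical data and reference masks and are not
reproducible here.

## Numerical conventions

* 0-based, half-open bounding boxes; image row index top→down.
* "Left lung" is image-left (patient's right side).
* Dice of two empty masks, thresholds of constant images, profiles of
  sub-3-point boundaries, and empty-body surfaces raise typed errors
  rather than returning sentinels.
* All randomness flows through `numpy.random.default_rng` seeded from the
  spec or CLI `--seed`; pipeline runs record the config hash, seed,
  versions and per-stage timings in a manifest.
* Problem sizes in the test-suite and acceptance runs: 20 phantoms of
  40×256×256 voxels, one evaluated axial slice each; 100 random
  histograms for the threshold oracle; 20 random small bodies for the
  entry-search oracle; 16³ volumes for traversal oracles.
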