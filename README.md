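# nodulecad

Rule-based pre-diagnosis of pulmonary nodules on chest CT: lung parenchyma
segmentation, hand-crafted shape/gray feature screening of candidate
regions, 3-D reconstruction of the lung field, and straight-line biopsy
insertion-path planning — exercised end to end on synthetic thorax
phantoms with exact ground truth.

## Who this is for

Researchers and engineers building or evaluating classical (non-learned)
computer-aided detection pipelines for chest CT. The package implements a
complete screening chain the way an image-processing practitioner would
write it in the pre-deep-learning tradition, and ships a deterministic
phantom generator so every stage can be tested without access to clinical
data.

## The method

**Segmentation.** A slice is lightly denoised (truncated Gaussian, total
kernel width 6σ), then binarized with an adaptive threshold obtained by
fixed-point iteration: starting from T₀ = (g_max + g_min)/2, T is replaced
by the average of the mean grays below and above it until the update falls
under 10⁻³. Foreground (gray < T) contains the outside field, air and
parenchyma; 4-connected components are screened by area — the largest
component is the surrounding air and is discarded, then with descending
areas S₂ ≥ S₃ the rule *keep components with S₃ ≤ s ≤ S₂ when
S₂/S₃ ≤ λ (λ = 50), else keep only S₂* extracts the left/right lungs and
drops the trachea. Holes (vessels, nodules) are filled, each lung's
boundary is repaired morphologically (closing + opening with a disk,
light erosion), and the repaired mask multiplies the gray slice.
Segmentation quality is measured by the Dice coefficient
2|A∩B|/(|A|+|B|).

**Screening.** Bright blobs inside the masked parenchyma are candidate
regions. Each is described by area S_R, perimeter P_R (8-connected chain,
diagonals √2), quasi-roundness C_R = 4πS_R/P_R², marginal burr rate
MBR = n_b/n and magnitude MBM from the normalized radial-distance profile
of the boundary, gray mean GM, gray variance GV and gray entropy
GE = −Σ (A(k)/S_R) ln(A(k)/S_R). A region is a suspected nodule iff

    S_R ≥ 30  ∧  C_R ≥ 0.6  ∧  GM ≤ 196  ∧  GE ≥ 3.5  ∧  MBR ≥ 0.16

evaluated in that order (the first failing gate is the rejection reason);
suspected nodules with S_R ≥ 300 (≈ >10 mm diameter) are flagged large.
Detection is scored with sensitivity F_se = TP/(TP+FN), specificity
F_sp = TN/(FP+TN) (≡ 0 since a non-nodule is negative and TN = 0) and
accuracy F_a = TP/(TP+TN+FP+FN).

**Planning.** Slices are stacked into a voxel volume, optionally resampled
isotropically, and marching cubes extracts tissue surfaces. For a target
nodule centroid (x_l, y_l, z_l) the planner evaluates the distance to
every chest-surface point, keeps the k shortest candidate entries
(d_min = min √((x_i−x_l)² + (y_i−y_l)² + (z_i−z_l)²)), ranks them by the
cumulative gray Σg of the voxels on the straight path (3-D Bresenham),
and returns the lowest-gray-sum candidate that avoids all obstacle masks
(bone, key vessels).

## Worked example

```python
import nodulecad as nc
from nodulecad.io import detect_slice
from nodulecad.parenchyma import dice_coefficient

spec = nc.default_spec(seed=11)          # deterministic thorax phantom
vol, truth = nc.generate_phantom(spec)   # (40, 256, 256) voxels + truth masks
dets, seg, feats = detect_slice(vol[20], slice_index=20)

print(f"threshold = {seg.threshold:.1f}")
print(f"Dice vs truth = {dice_coefficient(seg.mask, truth.parenchyma[20]):.4f}")
for f, d in zip(feats, dets):
    label = "suspected-nodule" if d.suspected else f"rejected ({d.rejection_reason})"
    print(f"region @({f.centroid[0]:5.1f},{f.centroid[1]:5.1f})  S={f.s_r:5.0f} "
          f"C={f.c_r:.3f}  MBR={f.mbr:.3f}  GM={f.gm:5.1f}  GE={f.ge:.2f}  -> {label}")
```

prints

```
threshold = 70.7
Dice vs truth = 0.9837
region @(103.6, 67.9)  S=  137 C=0.711  MBR=0.209  GM=154.3  GE=4.05  -> suspected-nodule
region @(109.2,167.0)  S=   41 C=1.228  MBR=0.111  GM=202.5  GE=3.05  -> rejected (GM)
region @(149.6,189.5)  S=  135 C=0.684  MBR=0.205  GM=158.9  GE=4.06  -> suspected-nodule
region @(156.5, 82.5)  S=  144 C=0.313  MBR=0.053  GM=162.7  GE=2.42  -> rejected (C)
```

The adaptive threshold lands between the dark classes (air/parenchyma)
and soft tissue; segmentation overlaps the true parenchyma at Dice 0.98.
Both spiculated nodules pass all five gates. The bright circular region
is a vessel running perpendicular to the slice — rejected because its
gray mean exceeds T_GM — and the elongated region is an in-plane vessel,
rejected at the quasi-roundness gate. No false positives remain.

A command-line interface mirrors the library:

```bash
nodulecad phantom --out work/phantom --seed 0      # volume + DICOM + truth
nodulecad run --out work/run --seed 0              # segment→detect→reconstruct→plan
nodulecad segment --in slice.png --out work/seg --ref ref_mask.png
nodulecad reconstruct --in work/phantom/dicom --iso 90 --out lung.stl
```

## Limitations

The phantom is a geometric stand-in (analytic ellipsoids, cylinders and
petal-margined spheres), not anatomy; see `docs/methods.md` for what
passing its tests does and does not demonstrate about clinical images.
Benign/malignant discrimination, learned classifiers and robot control
are out of scope.
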