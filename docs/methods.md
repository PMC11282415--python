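# Methods

## Overview

`ctmorph` measures five rotational/translational parameters of the hip and
knee from single axial CT slices: femoral version, acetabular anteversion,
trochlear sulcus angle, posterior condylar axis (PCA) angle and the
tibial tuberosity–trochlear groove (TT-TG) distance. The pipeline has three
stages — landmark-slice classification, bone segmentation, contour
morphometry — each usable on its own. Because no patient imaging ships with
the package, a phantom module renders axial bone cross-sections with
analytically known geometry; all quantitative validation is against those
phantoms.

## Coordinate conventions

One fixed frame everywhere: x = column index increasing rightward,
y = row index increasing downward, which is *posterior* on an axial slice
displayed anterior-up. Stacks and masks are resampled to 1 mm/pixel
in-plane before measurement (`resample_isotropic`; output extent
`round(px × spacing)`, bilinear for images, nearest-neighbour for masks so
they stay binary), so pixel coordinates are millimetres downstream. Axis
angles are folded into (−90°, 90°] versus the x-axis. Left limbs are
mirrored into a canonical right-limb frame before measurement; the sign
convention (positive version/anteversion = anteverted in that frame) is a
package convention, since axial-frame signs are not standardized.
The slice pitch is carried through metadata but never used: every
measurement is in-plane. Model-input resizing pads to a square before
scaling (never stretches), so angles survive the 256×256 resize; the
returned transform maps model-space points back to mm space.

## Morphometry

- **Best-fitting line** (femoral version): total least squares — the
  principal eigenvector of the foreground-pixel covariance, anchored at the
  centroid. TLS was chosen over y-on-x regression because the neck axis can
  be steep; the result is rotation-equivariant. Guards: `min_area` = 50 px
  (reject noise blobs), eigenvalue ratio ≥ 1.05 (reject isotropic masks
  with no meaningful axis).
- **Convex hull and convexity defects**: the hull of foreground pixel
  centres (`scipy.spatial.ConvexHull`); concavities are found by walking
  the largest closed boundary contour (`skimage.measure.find_contours` at
  the 0.5 level) between hull vertices that are consecutive along the
  contour, measuring perpendicular depth below each hull chord. Interior
  holes live on other contours and therefore cannot corrupt landmark
  geometry.
- **Trochlear landmarks**: the groove is the deepest *anterior* defect
  whose chord spans the centroid column; the ridges are its chord
  endpoints. The sulcus is the apex of the *most concave region*, not the
  single deepest point: the depth profile along the chord (1 mm bins of
  maximal depth) is minimum-filtered over a 9 mm window, the winning
  neighbourhood's near-deepest points (within 1 mm of maximal depth) are
  averaged, and the result is snapped to a boundary pixel. The width
  filter exists because a raster staircase or a narrow notch bitten out of
  the groove wall by imperfect segmentation can be locally deeper than the
  true sulcus; anatomy is wide, damage is narrow. On clean phantoms the
  plain argmax wanders ±2–3 px along the walls (≈2°/px of sulcus-angle
  sensitivity at phantom scale); the region apex stays within ~1 px.
- **PCA**: posterior boundary pixels are split by the centroid column; on
  each side the pixels within 1 mm of that side's maximal y are averaged.
  Averaging over the flat raster tangent of a round condyle halves the
  angular quantization error versus taking one corner pixel of the tangent
  row (≈0.1° versus ≈0.4° mean error on phantoms).
- **Tuberosity apex**: the most anterior boundary point, ties broken
  toward the centroid column.
- **TT-TG**: both points are orthogonally projected onto the PCA line; the
  reported distance is the distance between the projections, equivalently
  |(apex − groove)·û|.
- **Acetabular peaks**: the hull vertices bounding the deepest convexity
  defect anywhere on the boundary (the cup opening); anteversion is the
  angle of the peak chord versus vertical.
- `measure_all` composes the above; per-measurement failures (no groove,
  single condyle, empty mask, …) become explicit absence reasons and never
  abort the other measurements. A report never contains a silent zero.

## Classification

Nine ordered slice classes cover the anatomy an axial stack traverses;
the four landmark classes carry fixed ids (trochlea = 2, acetabulum = 4,
femoral neck = 6, tibial tuberosity = 8). Training data are curated from
annotated slice intervals: up to 10 slices per label per patient, evenly
spaced (`start + k·floor(n/10)`), every image also horizontally flipped so
left/right anatomy is balanced by construction, scarce classes topped up
(and abundant ones evenly subsampled) to a common per-class count with
randomly shifted (±12 px) and rescaled (0.9–1.1) copies. The feature
extractor is pluggable; the default is a handcrafted, fully offline
descriptor — a 16×16 mean-intensity grid plus an 8-orientation HOG over
32 px cells (768 dimensions) — so tests and examples never download
pretrained CNN weights; a CNN extractor can be registered under the same
contract. The classifier is an XGBoost multi-class ensemble
(`multi:softprob`, 60 rounds, depth 4, η = 0.3, single-threaded,
seeded; hyperparameters are package defaults, fixed in
`DEFAULT_XGB_PARAMS`). Landmark retrieval scores every slice and takes,
per target class, the index with the highest class probability (ties → the
lowest index); a maximum below 0.2 flags low confidence instead of raising,
so out-of-distribution stacks degrade to explicit absences.

Classifier metrics default to class-frequency-weighted averaging of
precision/recall/F1/Jaccard (macro available via flag); Hamming loss equals
1 − accuracy for single-label multiclass data and is computed
independently as a cross-check.

## Segmentation

The stage contract is: grayscale slice in, same-shape boolean mask out,
through a named backend registry. The bundled baseline is classical:
a three-level multi-Otsu global threshold (upper cut), hole filling, and
removal of components below 25 px. Two-level Otsu would merge the
soft-tissue halo with bone on trimodal slices; the upper multi-Otsu cut is
still a global, automatic, histogram-based threshold. Near-constant images
yield an empty mask with a warning. Deep backends (attention U-Net,
UNet3+, 2D TransUNet) are registered as contract placeholders without
weights; their architectures are documented elsewhere and out of scope
here. Metrics are per-image by default with a pixel-pooled variant
available; `bootstrap_mean_ci` aggregates per-image values with a
percentile bootstrap 95% CI. Two empty masks score Dice 1 with a flag —
an empty prediction of an empty truth is a correct prediction.

## Phantoms

Geometry is constructed in millimetres on a 256 mm canvas (256×256 px at
the default 1 mm/px; a `spacing` parameter renders the same anatomy at a
different pitch to exercise resampling) and rasterized with
`skimage.draw`. Every generator is a pure function of its parameters and
seed, and records both the requested scalars and the exact construction
points, so recovery tests can separate rasterization error from
algorithmic error:

- *femoral neck*: ellipse (90×28 mm) with its major axis at the requested
  version angle; an optional greater-trochanter lobe (radius 0.6× the neck
  half-width, perpendicular to the axis near one end) reproduces the
  documented lateral bias of best-fit-line version estimates — about 3.7°
  at the default lobe, bounded below 5° by test;
- *trochlea*: body polygon with ridges ±60 mm apart and groove depth
  60/tan(sulcus/2), plus two condyle disks (radius 22 mm) whose posterior
  tangent realizes the PCA angle; the whole construction is rotated rigidly
  for nonzero PCA;
- *tibial tuberosity*: ellipse (110×70 mm) with an anterior bump whose
  1 mm-blunted apex (sharp tips do not survive rasterization) sits at the
  requested offset from the canvas reference column;
- *acetabulum*: annular sector (radii 40/60 mm) whose rim-opening chord
  makes the requested angle with vertical (default gap 100°);
- *patient stack*: 9 contiguous class intervals in class order (axial
  stacks traverse sequential anatomy) with distinct filler primitives for
  the five non-landmark classes — geometric stand-ins, not anatomical
  claims. The tuberosity offset is solved so the trochlea/tuberosity pair
  realizes the requested TT-TG exactly along the requested PCA direction.
  Default parameters (version 15°, anteversion 17°, sulcus 140°, PCA 7°,
  TT-TG 10 mm) sit at the centres of the normal clinical ranges these
  measurements are validated against.

Pseudo-CT rendering: bone 220, a 6 px soft-tissue halo at 120, background
30, additive Gaussian noise of σ = 8 on the 8-bit scale (configurable).
`degrade_mask` perturbs masks for robustness studies: boundary recession by
disk erosion, plus random holes punched strictly in the interior (≥2 px
wall). The two knobs are orthogonal by design — a "hole" merging with the
exterior would be boundary damage under a different name, and hole chains
breaking through the boundary carve craters into the groove wall that no
contour method should be expected to see through.

## Validation design and problem sizes

- Clean-phantom recovery grids (version −30…40°, sulcus 120…160°,
  PCA 0…12°, TT-TG 0…25 mm, anteversion 0…30°): mean absolute error
  ≤ 1° / 1 mm (≤ 2° for the sulcus).
- Degraded masks (erosion 2 px, hole rate 0.02): mean errors must stay
  below the published automated-versus-manual mean errors for each
  measurement (3.72° version, 0.70° PCA, 2.01° anteversion, 2.44° sulcus,
  2.34 mm TT-TG) — the tool must agree with its own ground truth at least
  as well as the validated clinical pipeline agreed with a human expert.
- Brute-force oracles, ≥50 random instances each: an O(n³)-style hull by
  definition; an exhaustive boundary-pixel scan for the sulcus region; a
  morphological (hull-image difference) scan for the acetabular rim
  points; the closed form |Δ·û| for TT-TG; direct confusion counting for
  classifier metrics; a 10⁴-draw sign-flip permutation test against the
  paired t-test.
- Scaled-down cohort replication: 38 phantom patients with randomized
  morphometrics, 28 for training and 10 held out (27 slices per stack,
  168 curated images per class); retrieval must hit the true landmark
  interval for ≥90% of targets and end-to-end measurements must meet the
  degraded-mask budgets. Sizes were chosen so the full suite runs in a few
  minutes on one CPU while keeping ≥1500 training images.
- Invariances: rotation equivariance of all axis-referenced angles (±1°),
  rotation invariance of sulcus angle and TT-TG, mirror/laterality
  consistency (±0.5° / 0.5 mm), scale invariance of angles across
  rendering pitch, resample idempotence, and bitwise seed determinism.

## What the phantoms do and do not show

The phantoms have piecewise-analytic boundaries, uniform bright bone, and
a single tissue halo. Passing the suite demonstrates that the geometry is
implemented correctly, is robust to boundary erosion and interior holes,
and that the pipeline stages compose correctly — it does not demonstrate
performance on real arthritic CT, where bone density varies, joint spaces
collapse, osteophytes distort contours and the soft-tissue histogram is
not trimodal. The classifier's phantom accuracy in particular says nothing
about CT appearance models; it validates the curation/feature/boosting
machinery around whichever extractor a user registers.

## Known limitations

- Single-slice, in-plane measurements only; no 3D neck-axis referencing of
  the distal femur, no oblique (Swiss-axial) reformats, no cartilage-based
  TT-TG variant.
- The deep segmentation backends are contract placeholders; the baseline
  thresholder is not suitable for real arthritic CT.
- The paired comparison's t-test assumes roughly symmetric differences;
  the Wilcoxon option exists for heavier tails (the choice of test for the
  automated-versus-manual comparison is not standardized).
- Version sign conventions differ between clinics; the canonical-frame
  convention here is documented, not universal.
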