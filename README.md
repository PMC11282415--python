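# ctmorph

Automated hip and knee morphometry from axial CT slice stacks.

Preoperative CT measurements of rotational anatomy — femoral version,
acetabular anteversion, trochlear sulcus angle, posterior condylar axis
(PCA) angle, and the tibial tuberosity–trochlear groove (TT-TG) distance —
are routinely taken by hand, slice by slice, for arthroplasty and
femoroacetabular-impingement planning. `ctmorph` implements the three-stage
automated alternative as a Python library: a slice **classifier** finds the
four landmark slices in a stack of hundreds, a **segmenter** isolates the
bone as a binary mask, and a contour **morphometry** stage converts each
mask into a clinical measurement. A synthetic **phantom** generator renders
axial bone cross-sections with exactly known geometry, so every stage is
developed and validated without patient data. The intended users are
orthopaedic imaging researchers and engineers building or validating
CT-measurement pipelines.

## The measurements

All geometry lives in a single axial frame (x = column, rightward;
y = row, downward = posterior; 1 px = 1 mm after isotropic resampling;
left limbs mirrored to a canonical right-limb frame):

- **Femoral version** — the angle θ between the femoral neck's total
  least-squares line and the x-axis: the principal eigenvector of the
  foreground-pixel covariance Σ = cov(x, y), θ = atan2(v_y, v_x) folded
  into (−90°, 90°].
- **Sulcus angle** — the interior angle at the trochlear sulcus **S**
  between rays to the medial and lateral ridges **M**, **L**:
  cos α = (M−S)·(L−S) / (|M−S||L−S|). The ridges are the convex-hull
  vertices flanking the deepest anterior convexity defect; the sulcus is
  the most concave region of the boundary below the ridge chord.
- **PCA angle** — the angle of the line through the most posterior
  boundary point of each condyle (hull tangent points, one per side of the
  centroid column) versus the x-axis.
- **TT-TG distance** — with û the PCA unit direction, groove **G** and
  tuberosity apex **T**: TT-TG = |(T − G)·û|, i.e. the distance between
  the orthogonal projections of the two points onto the PCA line.
- **Acetabular anteversion** — the angle between the chord joining the two
  acetabular rim peaks (the hull points bounding the cup-opening defect)
  and the vertical axis.

Overlap metrics (Dice = 2|A∩B|/(|A|+|B|), mean IoU over foreground and
background classes, pixel accuracy) and multiclass classifier metrics
(accuracy, weighted precision/recall/F1/Jaccard, Hamming loss, confusion
matrix) are provided for evaluating the learned stages.

## Worked example

```python
from ctmorph import phantom
from ctmorph.morphometry import measure_all

_, _, truth = phantom.make_patient_stack(
    version_deg=15.0, anteversion_deg=17.0, sulcus_deg=140.0,
    pca_deg=7.0, tttg_mm=10.0, seed=7)
report = measure_all(phantom.truth_masks(truth), laterality="right")
```

prints, via `examples/02_measure_mask_set.py`:

```
measurement                     truth  measured
femoral version (deg)           15.00     14.88
acetabular anteversion (deg)    17.00     17.06
sulcus angle (deg)             140.00    140.71
PCA angle (deg)                  7.00      6.89
TT-TG distance (mm)             10.00      9.43
```

Each measured value is recovered purely from the rasterized mask; the
sub-degree / sub-millimetre residuals are rasterization error, the accuracy
floor of any contour method at 1 mm/pixel. The other scripts in
`examples/` walk through segmentation scoring, classifier training and
landmark retrieval, and the full pipeline with a paired
automated-versus-reference comparison table.

A thin CLI mirrors the library (`ctmorph phantom`, `train-classifier`,
`classify`, `segment`, `eval-seg`, `measure`, `run`, `compare`); see
`ctmorph --help`.

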