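"""Synthetic axial-slice phantoms with known ground-truth morphometrics.

No patient imaging ships with this package, so every stage — slice
classification, bone segmentation, and contour morphometry — is exercised
against geometric phantoms that emulate the axial bone cross-sections the
measurements are defined on:

* an elongated femoral-neck blob whose principal axis sits at a requested
  version angle (optionally with a greater-trochanter lobe, which is known to
  bias best-fit-line version estimates laterally);
* a distal-femur slice with two posterior condylar lobes (posterior condylar
  axis, PCA) and an anterior V-shaped trochlear groove (sulcus angle);
* a proximal tibia with an anterior tuberosity apex at a known offset, so a
  trochlea/tuberosity pair realises a known TT-TG distance;
* an acetabular crescent whose rim-opening chord sits at a known anteversion
  angle versus the vertical axis.

Five additional filler shapes complete a 9-class vocabulary so a full
pseudo-patient stack can be generated for classifier training: the class
shapes are distinct geometric stand-ins, not anatomical claims.  Target
classes follow the fixed numbering trochlea=2, acetabulum=4, femoral_neck=6,
tibial_tuberosity=8.

Every generator is a pure function of its parameters and an integer seed.
Ground truth is recorded twice: the requested scalar parameters, and the
exact construction points (in mm), so recovery tests can separate
rasterization error from algorithmic error.

Canvas convention: 256x256 px at 1 mm/px by default (the pipeline's
post-resampling world); anterior is row 0.  ``spacing`` renders the same
mm-scale geometry at a different pixel pitch to exercise resampling; truth
points are always in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as _draw_polygon
from skimage.morphology import dilation, disk, erosion

from ._geometry import rotate_points, unit_from_angle_deg
from .errors import CanvasError, DegradationError, ParameterError
from .imaging_io import BinaryMask, PixelSpacing, SliceStack

__all__ = [
    "PhantomTruth",
    "PhantomSlice",
    "CLASS_NAMES",
    "TARGET_CLASSES",
    "make_femoral_neck_phantom",
    "make_trochlea_phantom",
    "make_tibial_tuberosity_phantom",
    "make_acetabulum_phantom",
    "make_patient_stack",
    "degrade_mask",
    "render_pseudo_ct",
]

#: 9-class slice vocabulary; target landmark classes carry the fixed ids.
CLASS_NAMES = {
    0: "diaphysis",
    1: "distal_femur_body",
    2: "trochlea",
    3: "condylar_body",
    4: "acetabulum",
    5: "femoral_head",
    6: "femoral_neck",
    7: "tibial_plateau",
    8: "tibial_tuberosity",
}

TARGET_CLASSES = {"trochlea": 2, "acetabulum": 4, "femoral_neck": 6, "tibial_tuberosity": 8}


@dataclass
class PhantomTruth:
    """Ground-truth parameters of a generated phantom (the recovery oracle).

    ``points`` holds the exact construction landmarks in mm coordinates of
    the canonical (right-limb, anterior-up) frame.
    """

    version_deg: float | None = None
    anteversion_deg: float | None = None
    sulcus_deg: float | None = None
    pca_deg: float | None = None
    tttg_mm: float | None = None
    landmark_slice_index: dict[int, int] = field(default_factory=dict)
    seed: int = 0
    points: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sulcus_deg is not None and not (90.0 < self.sulcus_deg < 180.0):
            raise ParameterError(f"sulcus_deg must be in (90, 180), got {self.sulcus_deg}")
        if self.tttg_mm is not None and self.tttg_mm < 0:
            raise ParameterError("tttg_mm must be >= 0")
        for name in ("version_deg", "anteversion_deg", "sulcus_deg", "pca_deg", "tttg_mm"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ParameterError(f"{name} must be finite")
        if not set(self.landmark_slice_index) <= set(CLASS_NAMES):
            raise ParameterError("landmark_slice_index keys must be class ids 0-8")


@dataclass
class PhantomSlice:
    """One rendered slice: pseudo-CT image, ground-truth mask, class label."""

    image: np.ndarray
    mask: np.ndarray
    label: int
    truth: PhantomTruth | None = None

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ParameterError("image and mask dimensions differ")

    @property
    def binary_mask(self) -> BinaryMask:
        return BinaryMask(grid=self.mask)


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------

def render_pseudo_ct(mask: np.ndarray, noise_sd: float = 8.0, seed: int = 0,
                     halo_px: int = 6) -> np.ndarray:
    """Render a binary mask as a noisy pseudo-CT slice.

    Bone foreground is bright (220), a dilated soft-tissue halo mid-gray
    (120), background dark (30); additive Gaussian noise with configurable
    sigma on the 8-bit scale.
    """
    rng = np.random.default_rng(seed)
    img = np.full(mask.shape, 30.0)
    if halo_px > 0 and mask.any():
        img[dilation(mask, disk(halo_px))] = 120.0
    img[mask] = 220.0
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, mask.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _grids(canvas_px: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:canvas_px, 0:canvas_px]
    return xx.astype(float), yy.astype(float)


def _fill_polygon(points_px: np.ndarray, canvas_px: int) -> np.ndarray:
    mask = np.zeros((canvas_px, canvas_px), dtype=bool)
    rr, cc = _draw_polygon(points_px[:, 1], points_px[:, 0], shape=mask.shape)
    mask[rr, cc] = True
    return mask


def _fill_disk(center_px: np.ndarray, radius_px: float, canvas_px: int) -> np.ndarray:
    xx, yy = _grids(canvas_px)
    return (xx - center_px[0]) ** 2 + (yy - center_px[1]) ** 2 <= radius_px ** 2


def _check_canvas(points_mm: np.ndarray, canvas_mm: float, margin: float = 2.0) -> None:
    pts = np.atleast_2d(points_mm)
    if (pts < margin).any() or (pts > canvas_mm - margin).any():
        raise CanvasError("phantom shape exceeds the canvas")


# ---------------------------------------------------------------------------
# Individual landmark phantoms
# ---------------------------------------------------------------------------

def make_femoral_neck_phantom(version_deg: float, length_mm: float = 90.0,
                              width_mm: float = 28.0, trochanter: bool = False,
                              noise_sd: float = 8.0, seed: int = 0,
                              canvas_mm: float = 256.0,
                              spacing: float = 1.0) -> PhantomSlice:
    """Elongated convex blob whose principal axis makes ``version_deg`` with +x.

    ``trochanter=True`` attaches a lateral lobe near one end of the axis, the
    configuration that drags a best-fitting neck line laterally on real hips.
    """
    if not (length_mm > width_mm > 0):
        raise ParameterError("need length_mm > width_mm > 0")
    a, b = length_mm / 2.0, width_mm / 2.0
    th = math.radians(version_deg)
    cx = cy = canvas_mm / 2.0
    half_x = abs(a * math.cos(th)) + abs(b * math.sin(th))
    half_y = abs(a * math.sin(th)) + abs(b * math.cos(th))
    _check_canvas(np.array([[cx - half_x, cy - half_y], [cx + half_x, cy + half_y]]), canvas_mm)

    canvas_px = int(round(canvas_mm / spacing))
    xx, yy = _grids(canvas_px)
    dx = xx * spacing - cx
    dy = yy * spacing - cy
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    if trochanter:
        # lobe perpendicular to the axis near the lateral end
        end = np.array([cx, cy]) + 0.80 * a * unit_from_angle_deg(version_deg)
        perp = unit_from_angle_deg(version_deg + 90.0)
        lobe_c = end + 0.8 * b * perp
        lobe_r = 0.6 * b
        _check_canvas(lobe_c + lobe_r, canvas_mm)
        mask |= _fill_disk(lobe_c / spacing, lobe_r / spacing, canvas_px)

    truth = PhantomTruth(version_deg=float(version_deg), seed=seed,
                         points={"neck_center": (cx, cy)})
    image = render_pseudo_ct(mask, noise_sd=noise_sd, seed=seed)
    return PhantomSlice(image=image, mask=mask, label=TARGET_CLASSES["femoral_neck"], truth=truth)


def make_trochlea_phantom(sulcus_deg: float, pca_deg: float = 0.0,
                          condyle_radius_mm: float = 22.0, noise_sd: float = 8.0,
                          seed: int = 0, canvas_mm: float = 256.0,
                          spacing: float = 1.0) -> PhantomSlice:
    """Distal femur: two posterior condylar lobes plus an anterior V-groove.

    The posterior tangent line of the two condyle circles makes ``pca_deg``
    with +x; the ridge-sulcus-ridge angle at the groove equals ``sulcus_deg``
    by construction (ridges +-60 mm is fixed, groove depth derived).
    """
    if not (90.0 < sulcus_deg < 180.0):
        raise ParameterError(f"sulcus_deg must be in (90, 180), got {sulcus_deg}")
    if condyle_radius_mm <= 0:
        raise ParameterError("condyle_radius_mm must be positive")
    w = 60.0  # ridge half-separation, mm
    depth = w / math.tan(math.radians(sulcus_deg) / 2.0)
    if depth > 55.0:
        raise ParameterError("groove deeper than the phantom body (sulcus angle too acute)")

    cx = cy = canvas_mm / 2.0
    center = np.array([cx, cy])
    y_ridge = cy - 45.0
    ridge_l = np.array([cx - w, y_ridge])
    ridge_r = np.array([cx + w, y_ridge])
    sulcus = np.array([cx, y_ridge + depth])
    lat_l = np.array([cx - 70.0, cy - 5.0])
    lat_r = np.array([cx + 70.0, cy - 5.0])
    cond_l = np.array([cx - 50.0, cy + 28.0])
    cond_r = np.array([cx + 50.0, cy + 28.0])

    body = np.array([ridge_r, lat_r, cond_r, cond_l, lat_l, ridge_l, sulcus])
    body = rotate_points(body, pca_deg, center)
    conds = rotate_points(np.array([cond_l, cond_r]), pca_deg, center)
    ridge_l_rot, ridge_r_rot = rotate_points(np.array([ridge_l, ridge_r]), pca_deg, center)
    sulcus_rot = rotate_points(sulcus, pca_deg, center)
    _check_canvas(np.vstack([body, conds + condyle_radius_mm, conds - condyle_radius_mm]),
                  canvas_mm)

    canvas_px = int(round(canvas_mm / spacing))
    mask = _fill_polygon(body / spacing, canvas_px)
    mask |= _fill_disk(conds[0] / spacing, condyle_radius_mm / spacing, canvas_px)
    mask |= _fill_disk(conds[1] / spacing, condyle_radius_mm / spacing, canvas_px)

    # most-posterior point of a circle is centre + (0, R) irrespective of pca
    post_l = (float(conds[0][0]), float(conds[0][1] + condyle_radius_mm))
    post_r = (float(conds[1][0]), float(conds[1][1] + condyle_radius_mm))
    truth = PhantomTruth(
        sulcus_deg=float(sulcus_deg), pca_deg=float(pca_deg), seed=seed,
        points={
            "sulcus": tuple(sulcus_rot), "medial_ridge": tuple(ridge_l_rot),
            "lateral_ridge": tuple(ridge_r_rot),
            "condyle_posterior_1": post_l, "condyle_posterior_2": post_r,
        },
    )
    image = render_pseudo_ct(mask, noise_sd=noise_sd, seed=seed)
    return PhantomSlice(image=image, mask=mask, label=TARGET_CLASSES["trochlea"], truth=truth)


def make_tibial_tuberosity_phantom(apex_offset_mm: float, noise_sd: float = 8.0,
                                   seed: int = 0, canvas_mm: float = 256.0,
                                   spacing: float = 1.0) -> PhantomSlice:
    """Proximal tibia: ellipse with an anterior tuberosity apex.

    The apex column sits ``apex_offset_mm`` from the canvas reference column
    (the canvas centre); the apex is the unique most-anterior point.
    """
    cx = cy = canvas_mm / 2.0
    ax, ay = 55.0, 35.0
    apex = np.array([cx + apex_offset_mm, cy - 52.0])
    base_y = cy - 20.0
    _check_canvas(np.array([apex, [cx - ax, cy - ay], [cx + ax, cy + ay],
                            [apex[0] - 14.0, base_y], [apex[0] + 14.0, base_y]]), canvas_mm)
    canvas_px = int(round(canvas_mm / spacing))
    xx, yy = _grids(canvas_px)
    mask = (((xx * spacing - cx) / ax) ** 2 + ((yy * spacing - cy) / ay) ** 2) <= 1.0
    # slightly blunted apex (1 mm flat) so the tip survives rasterization
    bump = np.array([[apex[0] - 14.0, base_y], [apex[0] - 1.0, apex[1]],
                     [apex[0] + 1.0, apex[1]], [apex[0] + 14.0, base_y]])
    mask |= _fill_polygon(bump / spacing, canvas_px)

    truth = PhantomTruth(seed=seed, points={"tuberosity_apex": tuple(apex),
                                            "reference_column": (cx, cy)})
    image = render_pseudo_ct(mask, noise_sd=noise_sd, seed=seed)
    return PhantomSlice(image=image, mask=mask,
                        label=TARGET_CLASSES["tibial_tuberosity"], truth=truth)


def make_acetabulum_phantom(anteversion_deg: float, rim_gap_deg: float = 100.0,
                            noise_sd: float = 8.0, seed: int = 0,
                            canvas_mm: float = 256.0,
                            spacing: float = 1.0) -> PhantomSlice:
    """Acetabular crescent (annular sector) with a rim opening.

    The chord joining the two rim endpoints makes ``anteversion_deg`` with
    the vertical (y) axis: at 0 deg the rim endpoints share a column, and a
    positive angle tilts the opening as an anteverted cup does in the
    canonical right-limb frame.
    """
    if not (20.0 < rim_gap_deg < 180.0):
        raise ParameterError(f"rim_gap_deg must be in (20, 180), got {rim_gap_deg}")
    R, r = 60.0, 40.0
    g = math.radians(rim_gap_deg) / 2.0
    phi = math.radians(anteversion_deg)
    cx = cy = canvas_mm / 2.0
    _check_canvas(np.array([[cx - R, cy - R], [cx + R, cy + R]]), canvas_mm)

    canvas_px = int(round(canvas_mm / spacing))
    xx, yy = _grids(canvas_px)
    dx = xx * spacing - cx
    dy = yy * spacing - cy
    rad = np.hypot(dx, dy)
    ang = np.arctan2(dy, dx)
    diff = np.angle(np.exp(1j * (ang - phi)))  # wrapped angular distance from bisector
    mask = (rad >= r) & (rad <= R) & (np.abs(diff) >= g)

    p1 = (cx + R * math.cos(phi - g), cy + R * math.sin(phi - g))
    p2 = (cx + R * math.cos(phi + g), cy + R * math.sin(phi + g))
    peaks = sorted([p1, p2], key=lambda p: p[1])  # peak_1 = more anterior (smaller y)
    truth = PhantomTruth(anteversion_deg=float(anteversion_deg), seed=seed,
                         points={"acetabular_peak_1": peaks[0], "acetabular_peak_2": peaks[1]})
    image = render_pseudo_ct(mask, noise_sd=noise_sd, seed=seed)
    return PhantomSlice(image=image, mask=mask, label=TARGET_CLASSES["acetabulum"], truth=truth)


# ---------------------------------------------------------------------------
# Filler classes and whole-patient stacks
# ---------------------------------------------------------------------------

def _filler_mask(label: int, canvas_px: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Distinct geometric primitive per non-target class, with mild size jitter."""
    c = canvas_px * spacing / 2.0
    jit = rng.uniform(0.92, 1.08)

    def disk_at(center, radius):
        return _fill_disk(np.asarray(center, dtype=float) / spacing, radius / spacing, canvas_px)

    if label == 0:  # diaphysis: compact disk with a medullary hole
        return disk_at((c, c), 30.0 * jit) & ~disk_at((c, c), 12.0 * jit)
    if label == 1:  # distal femur body: wide flat ellipse
        xx, yy = _grids(canvas_px)
        return (((xx * spacing - c) / (62.0 * jit)) ** 2
                + ((yy * spacing - c) / (28.0 * jit)) ** 2) <= 1.0
    if label == 3:  # condylar body: two large overlapping lobes
        return disk_at((c - 33.0, c), 34.0 * jit) | disk_at((c + 33.0, c), 34.0 * jit)
    if label == 5:  # femoral head: large ball with trochanter tip
        return disk_at((c, c), 42.0 * jit) | disk_at((c + 56.0, c), 11.0 * jit)
    if label == 7:  # tibial plateau: rounded rectangle
        xx, yy = _grids(canvas_px)
        return (np.abs(xx * spacing - c) <= 44.0 * jit) & (np.abs(yy * spacing - c) <= 27.0 * jit)
    raise ParameterError(f"label {label} is not a filler class")


def make_patient_stack(version_deg: float = 15.0, anteversion_deg: float = 17.0,
                       sulcus_deg: float = 140.0, pca_deg: float = 7.0,
                       tttg_mm: float = 10.0, n_slices: int = 27, seed: int = 0,
                       laterality: str = "right", patient_id: str = "",
                       noise_sd: float = 8.0, canvas_mm: float = 256.0,
                       spacing: float = 1.0) -> tuple[SliceStack, list[int], PhantomTruth]:
    """Render a full pseudo-patient stack covering all 9 slice classes.

    Classes occupy contiguous intervals in increasing class order (axial
    stacks traverse sequential anatomy), each with a class-distinctive shape;
    the four target classes embed the parameterized landmark phantoms.  The
    tuberosity apex offset is solved so that the trochlea/tuberosity pair
    realises exactly ``tttg_mm`` along the requested PCA direction.

    Returns the grayscale :class:`SliceStack`, the per-slice labels, and the
    :class:`PhantomTruth` with landmark slice indices and construction points.
    """
    if n_slices < 18:
        raise ParameterError("n_slices must be >= 18 (at least 2 slices per class)")
    if laterality not in ("left", "right"):
        raise ParameterError("laterality must be 'left' or 'right'")
    rng = np.random.default_rng(seed)

    troch = make_trochlea_phantom(sulcus_deg, pca_deg, noise_sd=0.0, seed=seed,
                                  canvas_mm=canvas_mm, spacing=spacing)
    sx, sy = troch.truth.points["sulcus"]
    u = unit_from_angle_deg(pca_deg)
    cx = cy = canvas_mm / 2.0
    apex_y = cy - 52.0
    # solve apex offset d so |((cx+d, apex_y) - sulcus) . u| == tttg_mm
    d = (tttg_mm - (apex_y - sy) * u[1]) / u[0] - (cx - sx)
    tub = make_tibial_tuberosity_phantom(d, noise_sd=0.0, seed=seed,
                                         canvas_mm=canvas_mm, spacing=spacing)
    acet = make_acetabulum_phantom(anteversion_deg, noise_sd=0.0, seed=seed,
                                   canvas_mm=canvas_mm, spacing=spacing)
    neck = make_femoral_neck_phantom(version_deg, noise_sd=0.0, seed=seed,
                                     canvas_mm=canvas_mm, spacing=spacing)
    target_masks = {2: troch.mask, 4: acet.mask, 6: neck.mask, 8: tub.mask}

    base, extra = divmod(n_slices, 9)
    sizes = [base + (1 if k < extra else 0) for k in range(9)]
    labels: list[int] = []
    for k, sz in enumerate(sizes):
        labels.extend([k] * sz)

    canvas_px = int(round(canvas_mm / spacing))
    images = np.zeros((n_slices, canvas_px, canvas_px), dtype=np.float64)
    landmark_index: dict[int, int] = {}
    starts = np.cumsum([0] + sizes[:-1])
    for k, (start, sz) in enumerate(zip(starts, sizes)):
        landmark_index[k] = int(start + sz // 2)
    for i, label in enumerate(labels):
        if label in target_masks:
            mask = target_masks[label]
        else:
            mask = _filler_mask(label, canvas_px, spacing, rng)
        slice_seed = int(rng.integers(0, 2**31 - 1))
        images[i] = render_pseudo_ct(mask, noise_sd=noise_sd, seed=slice_seed)

    if laterality == "left":
        images = images[:, :, ::-1].copy()

    points = dict(troch.truth.points)
    points.update(tub.truth.points)
    points.update(acet.truth.points)
    points.update(neck.truth.points)
    truth = PhantomTruth(
        version_deg=float(version_deg), anteversion_deg=float(anteversion_deg),
        sulcus_deg=float(sulcus_deg), pca_deg=float(pca_deg), tttg_mm=float(tttg_mm),
        landmark_slice_index=landmark_index, seed=seed, points=points,
    )
    stack = SliceStack(slices=images, spacing=PixelSpacing(spacing, spacing, 1.0),
                       laterality=laterality, patient_id=patient_id or f"phantom-{seed}")
    return stack, labels, truth


def truth_masks(truth: PhantomTruth, canvas_mm: float = 256.0,
                spacing: float = 1.0) -> dict[int, BinaryMask]:
    """Re-render the four noiseless target-class masks for a stack truth."""
    troch = make_trochlea_phantom(truth.sulcus_deg, truth.pca_deg, noise_sd=0.0,
                                  seed=truth.seed, canvas_mm=canvas_mm, spacing=spacing)
    apex_x, _ = truth.points["tuberosity_apex"]
    tub = make_tibial_tuberosity_phantom(apex_x - canvas_mm / 2.0, noise_sd=0.0,
                                         seed=truth.seed, canvas_mm=canvas_mm, spacing=spacing)
    acet = make_acetabulum_phantom(truth.anteversion_deg, noise_sd=0.0, seed=truth.seed,
                                   canvas_mm=canvas_mm, spacing=spacing)
    neck = make_femoral_neck_phantom(truth.version_deg, noise_sd=0.0, seed=truth.seed,
                                     canvas_mm=canvas_mm, spacing=spacing)
    sp = PixelSpacing(spacing, spacing, 1.0)
    return {2: BinaryMask(troch.mask, sp), 4: BinaryMask(acet.mask, sp),
            6: BinaryMask(neck.mask, sp), 8: BinaryMask(tub.mask, sp)}


# ---------------------------------------------------------------------------
# Mask degradation (robustness testing)
# ---------------------------------------------------------------------------

def degrade_mask(mask: BinaryMask, erosion_px: int = 0, hole_rate: float = 0.0,
                 seed: int = 0) -> BinaryMask:
    """Perturb a mask boundary (erosion) and punch random interior holes.

    Emulates imperfect bone segmentations so morphometry robustness can be
    quantified against clean ground truth.  The two effects are orthogonal
    by construction: ``erosion_px`` controls how far the boundary recedes,
    while holes are punched strictly inside the (eroded) foreground — a
    "hole" that merged with the exterior would be boundary damage, not a
    hole, and would conflate the two knobs.
    """
    if not mask.grid.any():
        raise DegradationError("cannot degrade an empty mask")
    if erosion_px < 0 or not (0.0 <= hole_rate <= 1.0):
        raise ParameterError("erosion_px must be >= 0 and hole_rate in [0, 1]")
    g = mask.grid.copy()
    if erosion_px > 0:
        g = erosion(g, disk(erosion_px))
    if hole_rate > 0:
        rng = np.random.default_rng(seed)
        interior = erosion(g, disk(3))  # keep a >=2 px wall between holes and exterior
        seeds = (rng.random(g.shape) < hole_rate) & interior
        g &= ~dilation(seeds, disk(1))
    if not g.any():
        raise DegradationError("degradation emptied the mask")
    return BinaryMask(grid=g, spacing=mask.spacing,
                      source_slice_index=mask.source_slice_index)
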