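"""Contour-based morphometry of binary landmark masks.

The five clinical measurements are computed from convex-hull and best-fit
line geometry on single axial masks, all in the canonical frame (x right,
y down = posterior, right-limb; left-limb masks are mirrored first, and all
masks are at 1 mm/pixel so pixels are millimetres):

* **femoral version** — angle of the femoral neck's best-fitting (total
  least squares) line versus the x-axis, transversal single-slice method;
* **sulcus angle** — interior angle at the trochlear sulcus (the deepest
  point of the anterior convexity defect) between the two flanking ridge
  hull points;
* **posterior condylar axis (PCA) angle** — angle versus x of the line
  through the most posterior hull point of each condyle;
* **TT-TG distance** — distance between the orthogonal projections of the
  tibial tuberosity apex and the trochlear groove onto the PCA line;
* **acetabular anteversion** — angle between the chord joining the two
  acetabular rim peaks (the hull points bounding the cup opening) and the
  vertical axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import find_contours
from skimage.morphology import erosion

from ._geometry import angle_of_vector_deg, fold_angle_deg
from .errors import (
    AmbiguousAxisError,
    DegenerateHullError,
    DegenerateMaskError,
    NoGrooveError,
    NoOpeningError,
    SingleCondyleError,
)
from .imaging_io import MEASUREMENT_FIELDS, BinaryMask, resample_isotropic

__all__ = [
    "Axis2D",
    "MeasurementReport",
    "principal_axis",
    "femoral_version_angle",
    "convex_hull_points",
    "convexity_defects",
    "trochlear_landmarks",
    "sulcus_angle",
    "condylar_tangent_points",
    "posterior_condylar_axis",
    "tibial_tuberosity_apex",
    "tt_tg_distance",
    "acetabular_peaks",
    "acetabular_anteversion",
    "measure_all",
]


@dataclass(frozen=True)
class Axis2D:
    """A line in the plane: anchor point, unit direction, folded angle."""

    point: tuple[float, float]
    direction: tuple[float, float]
    angle_deg: float

    @classmethod
    def through(cls, p: tuple[float, float], q: tuple[float, float]) -> "Axis2D":
        d = np.array(q, dtype=float) - np.array(p, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise DegenerateMaskError("axis endpoints coincide")
        d = d / n
        return cls(point=tuple(np.asarray(p, dtype=float)), direction=(float(d[0]), float(d[1])),
                   angle_deg=fold_angle_deg(angle_of_vector_deg(d[0], d[1])))


@dataclass
class MeasurementReport:
    """The five measurements plus the landmarks and slices that produced them.

    Absent measurements are explicitly flagged in ``absent`` (name -> reason)
    and their value fields stay ``None`` — never silently zero.
    """

    femoral_version_deg: float | None = None
    acetabular_anteversion_deg: float | None = None
    sulcus_angle_deg: float | None = None
    pca_angle_deg: float | None = None
    tttg_mm: float | None = None
    landmarks: dict[str, tuple[float, float]] = field(default_factory=dict)
    source_slices: dict[str, int] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    absent: dict[str, str] = field(default_factory=dict)
    patient_id: str = ""
    laterality: str = "right"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sulcus_angle_deg is not None and not (90.0 < self.sulcus_angle_deg < 180.0):
            raise DegenerateMaskError(
                f"sulcus angle {self.sulcus_angle_deg:.2f} outside (90, 180)")
        if self.tttg_mm is not None and self.tttg_mm < 0:
            raise DegenerateMaskError("TT-TG distance must be >= 0")

    #: maps measurement field -> source-slice key
    _SLICE_KEYS = {
        "sulcus_angle_deg": "trochlea", "pca_angle_deg": "trochlea",
        "tttg_mm": "tibial_tuberosity", "femoral_version_deg": "femoral_neck",
        "acetabular_anteversion_deg": "acetabulum",
    }

    def iter_rows(self):
        for name, units in MEASUREMENT_FIELDS:
            yield name, units, getattr(self, name), self.source_slices.get(self._SLICE_KEYS[name])

    def to_dict(self) -> dict:
        return {
            "measurements": {
                name: {"value": value, "units": units, "slice_index": idx,
                       "absent_reason": self.absent.get(name)}
                for name, units, value, idx in self.iter_rows()
            },
            "landmarks": {k: list(v) for k, v in self.landmarks.items()},
            "source_slices": self.source_slices,
            "timings_s": self.timings_s,
            "patient_id": self.patient_id,
            "laterality": self.laterality,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementReport":
        kwargs = {name: d["measurements"][name]["value"] for name, _ in MEASUREMENT_FIELDS}
        absent = {name: d["measurements"][name].get("absent_reason")
                  for name, _ in MEASUREMENT_FIELDS
                  if d["measurements"][name].get("absent_reason")}
        return cls(
            **kwargs,
            landmarks={k: tuple(v) for k, v in d.get("landmarks", {}).items()},
            source_slices=d.get("source_slices", {}),
            timings_s=d.get("timings_s", {}),
            absent=absent,
            patient_id=d.get("patient_id", ""),
            laterality=d.get("laterality", "right"),
            seed=d.get("seed"),
        )


# ---------------------------------------------------------------------------
# Primitive geometry
# ---------------------------------------------------------------------------

def _fg_xy(mask: BinaryMask) -> np.ndarray:
    rc = np.argwhere(mask.grid)
    return rc[:, ::-1].astype(float)  # (x, y)


def _centroid(mask: BinaryMask) -> np.ndarray:
    return _fg_xy(mask).mean(axis=0)


def _boundary_xy(grid: np.ndarray) -> np.ndarray:
    inner = erosion(grid)
    rc = np.argwhere(grid & ~inner)
    return rc[:, ::-1].astype(float)


def _snap_to_boundary(point: np.ndarray, boundary_xy: np.ndarray) -> tuple[float, float]:
    i = int(np.argmin(((boundary_xy - point) ** 2).sum(axis=1)))
    return float(boundary_xy[i, 0]), float(boundary_xy[i, 1])


def principal_axis(mask: BinaryMask, min_area: int = 50,
                   isotropy_ratio: float = 1.05) -> Axis2D:
    """Total-least-squares line through the foreground: the principal
    eigenvector of the pixel-coordinate covariance, anchored at the centroid.

    Raises when the mask is too small to be meaningful or too isotropic for
    the axis direction to be well defined.
    """
    xy = _fg_xy(mask)
    if len(xy) < min_area:
        raise DegenerateMaskError(f"mask area {len(xy)} below min_area {min_area}")
    cov = np.cov(xy.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 0 or evals[1] / evals[0] < isotropy_ratio:
        raise AmbiguousAxisError(
            f"mask is nearly isotropic (eigenvalue ratio {evals[1] / max(evals[0], 1e-12):.3f})")
    d = evecs[:, 1]
    centroid = xy.mean(axis=0)
    return Axis2D(point=(float(centroid[0]), float(centroid[1])),
                  direction=(float(d[0]), float(d[1])),
                  angle_deg=fold_angle_deg(angle_of_vector_deg(d[0], d[1])))


def femoral_version_angle(neck_mask: BinaryMask, **kwargs) -> float:
    """Femoral version: signed angle of the neck's best-fitting line vs x-axis.

    Positive means anteverted in the canonical right-limb, anterior-up frame.
    """
    return principal_axis(neck_mask, **kwargs).angle_deg


def convex_hull_points(mask: BinaryMask) -> np.ndarray:
    """Convex hull of foreground pixel centres, ordered counter-clockwise as
    displayed (x right, y down), without duplicate vertices."""
    xy = _fg_xy(mask)
    if len(xy) < 3:
        raise DegenerateHullError("fewer than 3 foreground pixels")
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate (collinear) mask: {exc}") from exc
    # scipy orders 2D hull vertices counter-clockwise in a y-up frame, which
    # is clockwise on screen with y down; reverse for display order.
    return xy[hull.vertices][::-1]


#: contour points within this depth (mm) of a defect's maximal depth are
#: averaged into ``deep_region_centroid``; a raster staircase puts several
#: boundary points at near-identical depth, and the centroid of that region
#: locates a concavity apex far more stably than the single argmax point.
_DEEP_REGION_BAND = 1.0


@dataclass(frozen=True)
class ConvexityDefect:
    """One concavity: the hull chord bounding it and its deepest boundary point.

    ``deepest`` is the single point of maximal perpendicular depth below the
    chord; ``deep_region_centroid`` is the centroid of all boundary points
    within 1 mm of that depth (the "most concave region"); ``segment`` holds
    the boundary arc between the chord endpoints for finer analysis.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    deepest: tuple[float, float]
    depth: float
    deep_region_centroid: tuple[float, float] = (float("nan"), float("nan"))
    segment: np.ndarray | None = None


def _closed_contour(grid: np.ndarray) -> np.ndarray:
    contours = find_contours(grid.astype(float), 0.5)
    if not contours:
        raise DegenerateMaskError("mask has no boundary contour")
    c = max(contours, key=len)
    if np.allclose(c[0], c[-1]):
        c = c[:-1]
    return c[:, ::-1]  # (x, y)


def convexity_defects(grid: np.ndarray) -> list[ConvexityDefect]:
    """All convexity defects of the largest boundary contour.

    For each pair of hull vertices consecutive along the contour, the defect
    depth is the maximum perpendicular distance from the hull chord to the
    boundary arc between them.
    """
    cont = _closed_contour(grid)
    n = len(cont)
    if n < 3:
        raise DegenerateHullError("contour too short for a hull")
    try:
        hull = ConvexHull(cont)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate contour: {exc}") from exc
    hidx = np.sort(hull.vertices)
    defects: list[ConvexityDefect] = []
    for k in range(len(hidx)):
        a = hidx[k]
        b = hidx[(k + 1) % len(hidx)]
        if b > a:
            seg = cont[a + 1:b]
        else:  # wraparound
            seg = np.vstack([cont[a + 1:], cont[:b]])
        if len(seg) == 0:
            continue
        A, B = cont[a], cont[b]
        chord = B - A
        clen = np.linalg.norm(chord)
        if clen == 0:
            continue
        rel = seg - A
        depths = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / clen
        j = int(np.argmax(depths))
        near = seg[depths >= depths[j] - _DEEP_REGION_BAND]
        defects.append(ConvexityDefect(start=tuple(A), end=tuple(B),
                                       deepest=tuple(seg[j]), depth=float(depths[j]),
                                       deep_region_centroid=tuple(near.mean(axis=0)),
                                       segment=seg))
    return defects


#: features narrower than this (mm along the chord) are treated as boundary
#: damage, not anatomy, when locating a concavity apex
_MIN_FEATURE_WIDTH_MM = 9.0


def _robust_concavity_apex(defect: ConvexityDefect, band: float = _DEEP_REGION_BAND
                           ) -> np.ndarray:
    """Apex of a defect, insensitive to narrow bites in the boundary.

    The depth profile along the chord is minimum-filtered over a
    ``_MIN_FEATURE_WIDTH_MM`` window, so a deep but narrow notch (a
    segmentation hole or erosion artifact) cannot outrank the broad true
    concavity; the apex is then the centroid of the near-deepest points in
    the winning neighbourhood.
    """
    from scipy.ndimage import minimum_filter1d

    seg = defect.segment
    A = np.array(defect.start)
    ch = np.array(defect.end) - A
    clen = np.linalg.norm(ch)
    rel = seg - A
    t = rel @ ch / clen
    depth = np.abs(ch[0] * rel[:, 1] - ch[1] * rel[:, 0]) / clen
    bins = np.round(t).astype(int)
    lo, hi = bins.min(), bins.max()
    profile = np.zeros(hi - lo + 1)
    np.maximum.at(profile, bins - lo, depth)
    filtered = minimum_filter1d(profile, size=int(_MIN_FEATURE_WIDTH_MM), mode="nearest")
    t_star = float(np.argmax(filtered) + lo)
    cand = (np.abs(t - t_star) <= _MIN_FEATURE_WIDTH_MM / 4.0)
    cd = depth[cand]
    region = seg[cand][cd >= cd.max() - band]
    return region.mean(axis=0)


# ---------------------------------------------------------------------------
# Knee landmarks
# ---------------------------------------------------------------------------

def trochlear_landmarks(trochlea_mask: BinaryMask, min_depth_mm: float = 1.0
                        ) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float]]:
    """Locate (medial_ridge, lateral_ridge, sulcus) on a trochlear mask.

    The ridges are the hull vertices flanking the deepest *anterior*
    convexity defect, one on each side of the centroid column; the sulcus is
    the most concave region below the ridge chord — the centroid of the
    boundary points within 1 mm of maximal perpendicular depth, which is
    insensitive to the raster staircase at the groove apex.  Points are
    snapped to foreground boundary pixel centres.
    """
    cx, cy = _centroid(trochlea_mask)
    candidates = []
    for d in convexity_defects(trochlea_mask.grid):
        mid_y = (d.start[1] + d.end[1]) / 2.0
        spans = (d.start[0] - cx) * (d.end[0] - cx) < 0  # one ridge each side
        if mid_y < cy and spans and d.depth >= min_depth_mm:
            candidates.append(d)
    if not candidates:
        raise NoGrooveError(
            f"no anterior convexity defect deeper than {min_depth_mm} mm")
    best = max(candidates, key=lambda d: d.depth)
    boundary = _boundary_xy(trochlea_mask.grid)
    a = _snap_to_boundary(np.array(best.start), boundary)
    b = _snap_to_boundary(np.array(best.end), boundary)
    sulcus = _snap_to_boundary(_robust_concavity_apex(best), boundary)
    medial, lateral = sorted([a, b], key=lambda p: p[0])
    return medial, lateral, sulcus


def sulcus_angle(trochlea_mask: BinaryMask, min_depth_mm: float = 1.0) -> float:
    """Interior angle at the sulcus between rays to the two ridges, degrees."""
    medial, lateral, sulcus = trochlear_landmarks(trochlea_mask, min_depth_mm)
    v1 = np.array(medial) - np.array(sulcus)
    v2 = np.array(lateral) - np.array(sulcus)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def condylar_tangent_points(trochlea_mask: BinaryMask, band_mm: float = 1.0
                            ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Most posterior boundary point of each condyle (left, right of centroid).

    Posterior boundary pixels are split by the centroid column; on each side
    the pixels within ``band_mm`` of that side's maximal y are averaged.  The
    averaging lands on the centre of the flat raster tangent of a round lobe
    instead of one of its corner pixels, which halves the angular
    quantization error of the resulting axis.
    """
    cx, cy = _centroid(trochlea_mask)
    boundary = _boundary_xy(trochlea_mask.grid)
    posterior = boundary[boundary[:, 1] > cy]
    left = posterior[posterior[:, 0] < cx]
    right = posterior[posterior[:, 0] > cx]
    if len(left) == 0 or len(right) == 0:
        raise SingleCondyleError("posterior boundary points all on one side of the centroid")

    def tangent_point(side: np.ndarray) -> np.ndarray:
        ymax = side[:, 1].max()
        flat = side[side[:, 1] >= ymax - band_mm]
        return flat.mean(axis=0)

    p_left = tangent_point(left)
    p_right = tangent_point(right)
    if abs(p_left[0] - p_right[0]) < 1e-9:
        raise SingleCondyleError("condylar tangent points coincide in x")
    return (float(p_left[0]), float(p_left[1])), (float(p_right[0]), float(p_right[1]))


def posterior_condylar_axis(trochlea_mask: BinaryMask) -> Axis2D:
    """PCA: the line through the two condylar posterior tangent points,
    with its angle folded into (-90, 90] versus the x-axis."""
    p_left, p_right = condylar_tangent_points(trochlea_mask)
    return Axis2D.through(p_left, p_right)


def tibial_tuberosity_apex(tuberosity_mask: BinaryMask) -> tuple[float, float]:
    """Most anterior (min y) boundary point; ties go to the point whose
    column is closest to the mask centroid's column."""
    xy = _fg_xy(tuberosity_mask)
    if len(xy) == 0:
        raise DegenerateMaskError("empty tuberosity mask")
    cx = xy[:, 0].mean()
    ymin = xy[:, 1].min()
    top = xy[xy[:, 1] == ymin]
    order = np.lexsort((top[:, 0], np.abs(top[:, 0] - cx)))
    best = top[order[0]]
    return float(best[0]), float(best[1])


def tt_tg_distance(groove: tuple[float, float], apex: tuple[float, float],
                   pca: Axis2D) -> float:
    """TT-TG: distance between the orthogonal projections of the groove and
    the tuberosity apex onto the PCA line, i.e. ``|(apex - groove) . u_pca|``."""
    delta = np.array(apex, dtype=float) - np.array(groove, dtype=float)
    return float(abs(np.dot(delta, np.array(pca.direction))))


# ---------------------------------------------------------------------------
# Hip landmarks
# ---------------------------------------------------------------------------

def acetabular_peaks(acetabulum_mask: BinaryMask, min_depth_mm: float = 1.0
                     ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Rim endpoints of the cup opening: the hull vertices bounding the
    deepest convexity defect.  peak_1 is the more anterior (smaller y)."""
    defects = [d for d in convexity_defects(acetabulum_mask.grid) if d.depth >= min_depth_mm]
    if not defects:
        raise NoOpeningError(f"no convexity defect deeper than {min_depth_mm} mm")
    best = max(defects, key=lambda d: d.depth)
    boundary = _boundary_xy(acetabulum_mask.grid)
    a = _snap_to_boundary(np.array(best.start), boundary)
    b = _snap_to_boundary(np.array(best.end), boundary)
    p1, p2 = sorted([a, b], key=lambda p: p[1])
    return p1, p2


def acetabular_anteversion(acetabulum_mask: BinaryMask, min_depth_mm: float = 1.0) -> float:
    """Angle between the peak-connecting chord and the vertical (y) axis,
    signed positive for an anteverted opening in the canonical frame."""
    p1, p2 = acetabular_peaks(acetabulum_mask, min_depth_mm)
    vx = p2[0] - p1[0]
    vy = p2[1] - p1[1]
    return float(np.degrees(np.arctan2(-vx, vy)))


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

_LABEL_ALIASES = {2: "trochlea", 4: "acetabulum", 6: "femoral_neck", 8: "tibial_tuberosity",
                  "trochlea": "trochlea", "acetabulum": "acetabulum",
                  "femoral_neck": "femoral_neck", "tibial_tuberosity": "tibial_tuberosity"}


def _canonical_mask(mask: BinaryMask, laterality: str) -> BinaryMask:
    if not mask.spacing.is_isotropic_inplane:
        mask = resample_isotropic(mask)
    if laterality == "left":
        mask = BinaryMask(grid=mask.grid[:, ::-1].copy(), spacing=mask.spacing,
                          source_slice_index=mask.source_slice_index,
                          allow_empty=mask.allow_empty)
    return mask


def measure_all(masks: dict, laterality: str = "right", min_depth_mm: float = 1.0,
                patient_id: str = "") -> MeasurementReport:
    """Compute every available measurement from a label -> mask mapping.

    Keys may be class ids (2, 4, 6, 8) or names.  Left-limb masks are
    mirrored into the canonical right-limb frame first.  Per-measurement
    failures are collected as explicit absence reasons; one bad mask never
    suppresses the other measurements.
    """
    named: dict[str, BinaryMask] = {}
    for key, mask in masks.items():
        name = _LABEL_ALIASES.get(key)
        if name is None:
            raise DegenerateMaskError(f"unknown landmark label {key!r}")
        named[name] = _canonical_mask(mask, laterality)

    report = MeasurementReport(patient_id=patient_id, laterality=laterality)
    for name, mask in named.items():
        if mask.source_slice_index is not None:
            report.source_slices[name] = mask.source_slice_index

    groove = None
    pca = None
    if "trochlea" in named:
        mask = named["trochlea"]
        try:
            medial, lateral, sulcus = trochlear_landmarks(mask, min_depth_mm)
            groove = sulcus
            report.landmarks.update(medial_ridge=medial, lateral_ridge=lateral, sulcus=sulcus)
            report.sulcus_angle_deg = sulcus_angle(mask, min_depth_mm)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            report.absent["sulcus_angle_deg"] = str(exc)
        try:
            p_left, p_right = condylar_tangent_points(mask)
            pca = Axis2D.through(p_left, p_right)
            report.pca_angle_deg = pca.angle_deg
            report.landmarks["condyle_posterior_1"] = p_left
            report.landmarks["condyle_posterior_2"] = p_right
        except Exception as exc:  # noqa: BLE001
            report.absent["pca_angle_deg"] = str(exc)
    else:
        report.absent["sulcus_angle_deg"] = "landmark not found: trochlea mask absent"
        report.absent["pca_angle_deg"] = "landmark not found: trochlea mask absent"

    if "tibial_tuberosity" in named:
        try:
            apex = tibial_tuberosity_apex(named["tibial_tuberosity"])
            report.landmarks["tuberosity_apex"] = apex
            if groove is not None and pca is not None:
                report.tttg_mm = tt_tg_distance(groove, apex, pca)
            else:
                report.absent["tttg_mm"] = "TT-TG needs the trochlear groove and PCA"
        except Exception as exc:  # noqa: BLE001
            report.absent["tttg_mm"] = str(exc)
    else:
        report.absent["tttg_mm"] = "landmark not found: tibial tuberosity mask absent"

    if "femoral_neck" in named:
        try:
            report.femoral_version_deg = femoral_version_angle(named["femoral_neck"])
        except Exception as exc:  # noqa: BLE001
            report.absent["femoral_version_deg"] = str(exc)
    else:
        report.absent["femoral_version_deg"] = "landmark not found: femoral neck mask absent"

    if "acetabulum" in named:
        try:
            p1, p2 = acetabular_peaks(named["acetabulum"], min_depth_mm)
            report.landmarks.update(acetabular_peak_1=p1, acetabular_peak_2=p2)
            report.acetabular_anteversion_deg = acetabular_anteversion(
                named["acetabulum"], min_depth_mm)
        except Exception as exc:  # noqa: BLE001
            report.absent["acetabular_anteversion_deg"] = str(exc)
    else:
        report.absent["acetabular_anteversion_deg"] = "landmark not found: acetabulum mask absent"

    return report
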