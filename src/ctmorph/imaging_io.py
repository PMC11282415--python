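"""Reading, resampling and writing of axial CT slice stacks and masks.

All downstream geometry works in a single coordinate convention:

* ``x`` = column index, increasing rightward;
* ``y`` = row index, increasing downward — i.e. toward *posterior* on an
  axial slice displayed anterior-up;
* after :func:`resample_isotropic` one pixel is one millimetre, so pixel
  coordinates and mm coordinates coincide for every measurement.

DICOM series are read with :mod:`pydicom`; slices are ordered by the z
component of ``ImagePositionPatient`` when present, falling back to
``InstanceNumber``.  Masks travel as single-channel PNGs with foreground 255
and background 0, and measurement reports as JSON or CSV.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import FormatError, InputError, MetadataError

__all__ = [
    "PixelSpacing",
    "SliceStack",
    "BinaryMask",
    "ResizeTransform",
    "read_dicom_series",
    "write_dicom_series",
    "resample_isotropic",
    "resize_to_model_input",
    "read_mask_png",
    "write_mask_png",
    "write_report",
    "read_report",
    "MEASUREMENT_FIELDS",
]

#: the five clinical measurements, in report order, with their units
MEASUREMENT_FIELDS = (
    ("sulcus_angle_deg", "degrees"),
    ("pca_angle_deg", "degrees"),
    ("tttg_mm", "mm"),
    ("femoral_version_deg", "degrees"),
    ("acetabular_anteversion_deg", "degrees"),
)


@dataclass(frozen=True)
class PixelSpacing:
    """Physical size of one voxel: in-plane row/column pitch and slice pitch, mm."""

    row_mm: float
    col_mm: float
    slice_mm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("row_mm", "col_mm", "slice_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise MetadataError(f"PixelSpacing.{name} must be positive and finite, got {v!r}")

    @property
    def is_isotropic_inplane(self) -> bool:
        return np.isclose(self.row_mm, 1.0) and np.isclose(self.col_mm, 1.0)


ISOTROPIC = PixelSpacing(1.0, 1.0, 1.0)


@dataclass
class SliceStack:
    """An ordered stack of axial grayscale slices with spacing metadata."""

    slices: np.ndarray  # (n_slices, rows, cols)
    spacing: PixelSpacing
    laterality: str = "right"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise InputError("SliceStack needs a (n_slices, rows, cols) array with n_slices >= 1")
        if self.laterality not in ("left", "right"):
            raise InputError(f"laterality must be 'left' or 'right', got {self.laterality!r}")

    def __len__(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices.shape[1], self.slices.shape[2]


@dataclass
class BinaryMask:
    """A single 2D boolean mask with its in-plane spacing."""

    grid: np.ndarray
    spacing: PixelSpacing = ISOTROPIC
    source_slice_index: int | None = None
    allow_empty: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise InputError("BinaryMask grid must be 2D")
        if not self.allow_empty and not self.grid.any():
            raise InputError("BinaryMask has no foreground pixels (pass allow_empty=True to permit)")

    @property
    def area(self) -> int:
        return int(self.grid.sum())


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def read_dicom_series(path: str | Path) -> SliceStack:
    """Read an axial DICOM series from a directory into a :class:`SliceStack`.

    Slices are sorted by ``ImagePositionPatient[2]`` when available and by
    ``InstanceNumber`` otherwise, so the stack order reflects acquisition
    order regardless of file naming.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file()) if path.is_dir() else []
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise InputError(f"no readable DICOM files with pixel data in {path}")

    first = datasets[0]
    if "PixelSpacing" not in first:
        raise MetadataError("DICOM tag PixelSpacing (0028,0030) missing")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    slice_mm = float(getattr(first, "SliceThickness", 1.0) or 1.0)

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return (0, float(ipp[2]))
        return (1, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    arr = np.stack([ds.pixel_array for ds in datasets]).astype(np.float64)
    laterality = str(getattr(first, "Laterality", "") or "R")
    return SliceStack(
        slices=arr,
        spacing=PixelSpacing(row_mm, col_mm, slice_mm),
        laterality="left" if laterality.upper().startswith("L") else "right",
        patient_id=str(getattr(first, "PatientID", "")),
    )


def write_dicom_series(stack: SliceStack, path: str | Path) -> list[Path]:
    """Write a :class:`SliceStack` as one DICOM file per slice (secondary capture)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[stack.patient_id or "ctmorph", "series"])
    written = []
    for i, sl in enumerate(stack.slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[stack.patient_id or "ctmorph", f"slice{i}"]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.PatientID = stack.patient_id
        ds.Laterality = "L" if stack.laterality == "left" else "R"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * stack.spacing.slice_mm]
        ds.PixelSpacing = [stack.spacing.row_mm, stack.spacing.col_mm]
        ds.SliceThickness = stack.spacing.slice_mm
        ds.Rows, ds.Columns = sl.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.clip(np.round(sl), 0, 65535).astype(np.uint16).tobytes()
        out = path / f"slice_{i:04d}.dcm"
        ds.save_as(out, enforce_file_format=True)
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# Resampling and resizing
# ---------------------------------------------------------------------------

def _resample_grid(grid: np.ndarray, spacing: PixelSpacing, order: int) -> np.ndarray:
    rows, cols = grid.shape
    out_shape = (
        max(1, int(round(rows * spacing.row_mm))),
        max(1, int(round(cols * spacing.col_mm))),
    )
    if out_shape == (rows, cols) and spacing.is_isotropic_inplane:
        return grid.copy()
    return _sk_resize(
        grid.astype(float), out_shape, order=order, preserve_range=True, anti_aliasing=False
    )


def resample_isotropic(obj: SliceStack | BinaryMask):
    """Resample a stack or mask to 1 mm/pixel in-plane, preserving physical extent.

    Images are interpolated bilinearly, masks with nearest-neighbour so they
    stay binary.  Output pixel count per axis is ``round(in_px * spacing_mm)``.
    The slice pitch is carried through unchanged: every measurement in this
    package is in-plane, so slices are never resampled along z.
    """
    if isinstance(obj, BinaryMask):
        grid = _resample_grid(obj.grid.astype(float), obj.spacing, order=0) >= 0.5
        return BinaryMask(
            grid=grid,
            spacing=replace(obj.spacing, row_mm=1.0, col_mm=1.0),
            source_slice_index=obj.source_slice_index,
            allow_empty=obj.allow_empty,
        )
    if isinstance(obj, SliceStack):
        if obj.spacing.is_isotropic_inplane:
            return SliceStack(obj.slices.copy(), replace(obj.spacing, row_mm=1.0, col_mm=1.0),
                              obj.laterality, obj.patient_id)
        out = np.stack([_resample_grid(sl, obj.spacing, order=1) for sl in obj.slices])
        return SliceStack(out, replace(obj.spacing, row_mm=1.0, col_mm=1.0),
                          obj.laterality, obj.patient_id)
    raise InputError(f"cannot resample object of type {type(obj).__name__}")


@dataclass(frozen=True)
class ResizeTransform:
    """Invertible mapping between original-image and model-input coordinates.

    The original image is first centred on a square canvas of side
    ``pad_side`` (pure translation), then scaled to ``side``.  Angles are
    preserved because both steps are similarity transforms.
    """

    pad_top: int
    pad_left: int
    pad_side: int
    side: int

    @property
    def scale(self) -> float:
        return self.side / self.pad_side

    def to_model(self, point: tuple[float, float]) -> tuple[float, float]:
        x, y = point
        return ((x + self.pad_left) * self.scale, (y + self.pad_top) * self.scale)

    def to_original(self, point: tuple[float, float]) -> tuple[float, float]:
        x, y = point
        return (x / self.scale - self.pad_left, y / self.scale - self.pad_top)


def resize_to_model_input(image: np.ndarray, side: int = 256) -> tuple[np.ndarray, ResizeTransform]:
    """Pad an image to square, scale it to ``side`` x ``side``, and return the
    transform mapping model-space coordinates back to the original frame.

    Padding (with the image minimum) rather than anisotropic stretching keeps
    circles circular, so angles measured in model space remain valid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise InputError("resize_to_model_input needs a non-empty 2D image")
    if side <= 0:
        raise InputError("side must be positive")
    rows, cols = image.shape
    pad_side = max(rows, cols)
    pad_top = (pad_side - rows) // 2
    pad_left = (pad_side - cols) // 2
    canvas = np.full((pad_side, pad_side), image.min(), dtype=float)
    canvas[pad_top:pad_top + rows, pad_left:pad_left + cols] = image
    tfm = ResizeTransform(pad_top=pad_top, pad_left=pad_left, pad_side=pad_side, side=side)
    if pad_side == side:
        return canvas, tfm
    out = _sk_resize(canvas, (side, side), order=1, preserve_range=True, anti_aliasing=False)
    return out, tfm


# ---------------------------------------------------------------------------
# Mask PNG round trip
# ---------------------------------------------------------------------------

def write_mask_png(mask: BinaryMask, path: str | Path) -> Path:
    """Write a mask as a single-channel PNG with foreground 255."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((mask.grid.astype(np.uint8)) * 255, mode="L").save(path)
    return path


def read_mask_png(path: str | Path, spacing: PixelSpacing = ISOTROPIC) -> BinaryMask:
    """Read a 0/255 single-channel PNG as a :class:`BinaryMask`.

    Any pixel value other than 0 or 255 is a format error: a gray value would
    silently distort downstream geometry if thresholded.
    """
    arr = np.asarray(Image.open(path).convert("L"))
    values = np.unique(arr)
    if not set(values.tolist()) <= {0, 255}:
        bad = [v for v in values.tolist() if v not in (0, 255)]
        raise FormatError(f"mask PNG {path} contains non-binary values {bad[:5]}")
    return BinaryMask(grid=arr == 255, spacing=spacing, allow_empty=True)


# ---------------------------------------------------------------------------
# Measurement reports
# ---------------------------------------------------------------------------

def write_report(report, path: str | Path, format: str = "json") -> Path:
    """Serialize a MeasurementReport as JSON (full) or CSV (one row per measurement)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    elif format == "csv":
        # one row per *present* measurement; absences live in the JSON report
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "value", "units", "slice_index"])
            for name, units, value, slice_index in report.iter_rows():
                if value is None:
                    continue
                writer.writerow([name, f"{value:.6g}", units,
                                 "" if slice_index is None else slice_index])
    else:
        raise InputError(f"unknown report format {format!r}")
    return path


def read_report(path: str | Path):
    """Read a JSON measurement report back into a MeasurementReport."""
    from .morphometry import MeasurementReport  # late import: morphometry imports this module

    return MeasurementReport.from_dict(json.loads(Path(path).read_text()))


def report_rows_to_csv(rows: Iterable[tuple], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in rows:
            writer.writerow(row)
    return path
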