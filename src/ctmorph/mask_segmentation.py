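"""Bone segmentation contract, baseline backend, and overlap metrics.

The segmentation stage turns one grayscale axial slice into a binary bone
mask.  Deep backends (Attention U-Net, UNet3+, 2D TransUNet) are registry
entries honouring the same contract but ship no weights here; the bundled
baseline is a classical pipeline — automatic histogram-based global
threshold, hole filling, minimum-area component filtering — which is exact
on the bright-bone phantoms and serves as the deterministic stand-in for
pipeline testing.

Metrics follow the standard two-mask definitions:

* Dice = 2|A∩B| / (|A| + |B|) on the foreground;
* mean IoU = mean of foreground IoU and background IoU (the background term
  is what lets mean IoU exceed Dice on background-dominated frames);
* pixel accuracy = fraction of agreeing pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import remove_small_objects

from .errors import ConfigurationError, ContractError, InputError
from .imaging_io import ISOTROPIC, BinaryMask, PixelSpacing

__all__ = [
    "SegMetrics",
    "segment_slice",
    "evaluate_segmentation",
    "register_backend",
    "available_backends",
    "baseline_threshold_backend",
    "bootstrap_mean_ci",
]


@dataclass(frozen=True)
class SegMetrics:
    """Overlap metrics for one (predicted, truth) mask pair."""

    dice: float
    mean_iou: float
    pixel_accuracy: float
    fg_iou: float
    bg_iou: float
    both_empty: bool = False


# ---------------------------------------------------------------------------
# Backend registry
# ---------------------------------------------------------------------------

_BACKENDS: dict[str, Callable[[np.ndarray, dict], np.ndarray]] = {}


def register_backend(name: str, fn: Callable[[np.ndarray, dict], np.ndarray]) -> None:
    """Register a segmentation backend: (image, params) -> boolean grid."""
    _BACKENDS[name] = fn


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def baseline_threshold_backend(image: np.ndarray, params: dict) -> np.ndarray:
    """Classical baseline: global automatic threshold + hole fill + area filter.

    A three-level multi-Otsu threshold separates bone from the soft-tissue
    halo on trimodal slices (plain two-class Otsu would merge halo and bone);
    it falls back to two-class Otsu for bimodal images, and yields an empty
    mask for (near-)constant images.
    """
    min_area = int(params.get("min_area", 25))
    img = np.asarray(image, dtype=float)
    if np.ptp(img) < 1e-9:
        return np.zeros(img.shape, dtype=bool)
    try:
        thresholds = threshold_multiotsu(img, classes=3)
        thr = float(thresholds[-1])
    except ValueError:  # too few distinct values for 3 classes
        thr = float(threshold_otsu(img))
    mask = img > thr
    mask = ndimage.binary_fill_holes(mask)
    if min_area > 1:
        # max_size removes components smaller than or equal to the threshold
        mask = remove_small_objects(mask, max_size=min_area - 1)
    return mask


register_backend("baseline", baseline_threshold_backend)


def _unavailable_deep_backend(name: str) -> Callable[[np.ndarray, dict], np.ndarray]:
    def fn(image: np.ndarray, params: dict) -> np.ndarray:
        raise ConfigurationError(
            f"backend {name!r} is a contract placeholder: no trained weights are "
            "bundled; register an implementation or use 'baseline'")
    return fn


for _name in ("attention_unet", "unet3plus", "transunet2d"):
    register_backend(_name, _unavailable_deep_backend(_name))


def segment_slice(image: np.ndarray, backend: str = "baseline",
                  params: dict | None = None,
                  spacing: PixelSpacing = ISOTROPIC,
                  source_slice_index: int | None = None) -> BinaryMask:
    """Segment one grayscale slice into a bone mask with the named backend.

    An empty result is flagged with a warning rather than raised: downstream
    measurement reports it as an absent landmark.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InputError("segment_slice needs a 2D grayscale image")
    if backend not in _BACKENDS:
        raise ConfigurationError(
            f"unknown segmentation backend {backend!r}; available: {available_backends()}")
    grid = np.asarray(_BACKENDS[backend](img, params or {}))
    if grid.shape != img.shape or grid.dtype != bool:
        raise ContractError(
            f"backend {backend!r} returned {grid.dtype} array of shape {grid.shape}, "
            f"expected boolean of {img.shape}")
    if not grid.any():
        warnings.warn(f"backend {backend!r} produced an empty mask", stacklevel=2)
    return BinaryMask(grid=grid, spacing=spacing, source_slice_index=source_slice_index,
                      allow_empty=True)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate_segmentation(predicted: BinaryMask, truth: BinaryMask) -> SegMetrics:
    """Dice, mean (fg+bg) IoU and pixel accuracy for one mask pair.

    Both-empty pairs score Dice/IoU 1 by convention (flagged via
    ``both_empty`` and a warning): an empty prediction of an empty truth is
    a perfect prediction.
    """
    a = predicted.grid
    b = truth.grid
    if a.shape != b.shape:
        raise InputError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    n = a.size
    inter = int(np.logical_and(a, b).sum())
    union = int(np.logical_or(a, b).sum())
    sa, sb = int(a.sum()), int(b.sum())
    both_empty = sa == 0 and sb == 0
    if both_empty:
        warnings.warn("both masks empty: Dice/IoU defined as 1", stacklevel=2)
        dice = fg_iou = 1.0
    else:
        dice = 2.0 * inter / (sa + sb)
        fg_iou = inter / union if union else 1.0
    bg_inter = n - union
    bg_union = n - inter
    bg_iou = bg_inter / bg_union if bg_union else 1.0
    accuracy = float(np.mean(a == b))
    return SegMetrics(dice=float(dice), mean_iou=float((fg_iou + bg_iou) / 2.0),
                      pixel_accuracy=accuracy, fg_iou=float(fg_iou), bg_iou=float(bg_iou),
                      both_empty=both_empty)


def pooled_segmentation_metrics(pairs: list[tuple[BinaryMask, BinaryMask]]) -> SegMetrics:
    """Metrics pooled over the pixels of many pairs (alternative to the
    default per-image-then-average aggregation)."""
    if not pairs:
        raise InputError("no mask pairs")
    a = np.concatenate([p.grid.ravel() for p, _ in pairs])
    b = np.concatenate([t.grid.ravel() for _, t in pairs])
    return evaluate_segmentation(
        BinaryMask(a[None, :], allow_empty=True), BinaryMask(b[None, :], allow_empty=True))


def bootstrap_mean_ci(values: np.ndarray, n_boot: int = 2000, seed: int = 0,
                      alpha: float = 0.05) -> tuple[float, float, float]:
    """Mean with a percentile bootstrap (1-alpha) CI, for per-image metric
    aggregation in the style of segmentation benchmark tables."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputError("no values to aggregate")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(values.mean()), float(lo), float(hi)
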