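"""Landmark-slice classification over 9 axial slice classes.

An axial CT stack traverses the lower extremity in sequence, so every slice
can be assigned one of 9 ordered anatomical classes; four of them are the
measurement landmarks with fixed ids — trochlea = 2, acetabulum = 4,
femoral neck = 6, tibial tuberosity = 8.  The classifier pipeline is:

1. curate a labelled image set from annotated slice intervals (up to 10
   slices per label per patient, evenly distributed across the interval;
   every image also horizontally flipped to balance laterality; scarce
   classes topped up with randomly shifted/rescaled augmented copies);
2. extract a fixed-length feature vector per image through a pluggable
   extractor (the default is a handcrafted, fully offline descriptor:
   coarse 16x16 intensity grid plus a gradient-orientation histogram; a
   pretrained-CNN extractor can be registered under the same contract);
3. fit a gradient-boosted decision-tree ensemble (XGBoost) on the vectors;
4. at inference, score every slice of a stack and linearly scan the
   per-class probability arrays for the highest-probability slice of each
   target label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from skimage.feature import hog
from skimage.transform import resize as _sk_resize
from sklearn.metrics import (
    confusion_matrix,
    hamming_loss as _sk_hamming,
    jaccard_score,
    precision_recall_fscore_support,
)
import xgboost as xgb

from .errors import (
    ConfigurationError,
    CurationError,
    InputError,
    IntervalError,
    ParameterError,
    StateError,
    TrainingError,
)
from .imaging_io import SliceStack, resize_to_model_input

__all__ = [
    "N_CLASSES",
    "TARGET_LABELS",
    "LandmarkLabel",
    "AnnotatedInterval",
    "FeatureVector",
    "ClassifierMetrics",
    "CuratedDataset",
    "RetrievedSlice",
    "ClassifierModel",
    "select_even_interval",
    "augment_image",
    "curate_dataset",
    "register_extractor",
    "available_extractors",
    "extract_features",
    "extract_feature_matrix",
    "fit_classifier",
    "predict_probabilities",
    "retrieve_landmark_slices",
    "evaluate_classifier",
]

N_CLASSES = 9
#: fixed target-class numbering
TARGET_LABELS = {"trochlea": 2, "acetabulum": 4, "femoral_neck": 6, "tibial_tuberosity": 8}


@dataclass(frozen=True)
class LandmarkLabel:
    id: int
    name: str

    def __post_init__(self) -> None:
        if not 0 <= self.id < N_CLASSES:
            raise ParameterError(f"label id must be 0-8, got {self.id}")


@dataclass(frozen=True)
class AnnotatedInterval:
    """A manually annotated inclusive slice interval for one label."""

    patient_id: str
    label: int
    start_slice: int
    end_slice: int

    def __post_init__(self) -> None:
        if self.start_slice > self.end_slice:
            raise IntervalError(
                f"interval start {self.start_slice} > end {self.end_slice}")
        if not 0 <= self.label < N_CLASSES:
            raise ParameterError(f"label must be 0-8, got {self.label}")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    extractor_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise InputError("feature vector contains non-finite values")


@dataclass(frozen=True)
class ClassifierMetrics:
    """Single-label multiclass evaluation bundle (incl. 9x9 confusion matrix)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    jaccard: float
    hamming_loss: float
    confusion: np.ndarray
    average: str = "weighted"


@dataclass
class CuratedDataset:
    images: np.ndarray  # (n, side, side) float32
    labels: np.ndarray  # (n,)
    manifest: pd.DataFrame  # patient_id, label, slice_index, transform

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RetrievedSlice:
    index: int
    probability: float
    low_confidence: bool


# ---------------------------------------------------------------------------
# Slice selection and augmentation
# ---------------------------------------------------------------------------

def select_even_interval(start: int, end: int, cap: int = 10) -> list[int]:
    """Up to ``cap`` slice indices evenly distributed over [start, end].

    With interval length n <= cap every index is returned; otherwise the cap
    indices are ``start + k * floor(n / cap)`` for k = 0..cap-1, e.g. the
    interval 0-50 with cap 10 yields [0, 5, 10, 15, 20, 25, 30, 35, 40, 45].
    """
    if start > end:
        raise IntervalError(f"start {start} > end {end}")
    if cap < 1:
        raise ParameterError("cap must be >= 1")
    n = end - start + 1
    if n <= cap:
        return list(range(start, end + 1))
    step = n // cap
    return [start + k * step for k in range(cap)]


def augment_image(image: np.ndarray, max_shift_px: int = 12,
                  scale_range: tuple[float, float] = (0.9, 1.1),
                  seed: int = 0) -> np.ndarray:
    """Random shift + random rescale, output dimensions preserved by crop/pad."""
    lo, hi = scale_range
    if not (0.5 < lo <= hi < 2.0):
        raise ParameterError(f"scale_range must satisfy 0.5 < lo <= hi < 2.0, got {scale_range}")
    if max_shift_px < 0:
        raise ParameterError("max_shift_px must be >= 0")
    img = np.asarray(image, dtype=float)
    rows, cols = img.shape
    rng = np.random.default_rng(seed)
    dy, dx = rng.integers(-max_shift_px, max_shift_px + 1, size=2) if max_shift_px else (0, 0)
    scale = float(rng.uniform(lo, hi))

    out = img
    if not np.isclose(scale, 1.0):
        new_shape = (max(1, round(rows * scale)), max(1, round(cols * scale)))
        scaled = _sk_resize(out, new_shape, order=1, preserve_range=True, anti_aliasing=False)
        out = np.full((rows, cols), img.min(), dtype=float)
        # centre crop or pad back to the original frame
        r0 = (new_shape[0] - rows) // 2
        c0 = (new_shape[1] - cols) // 2
        rs, cs = max(0, r0), max(0, c0)
        rd, cd = max(0, -r0), max(0, -c0)
        h = min(rows - rd, new_shape[0] - rs)
        w = min(cols - cd, new_shape[1] - cs)
        out[rd:rd + h, cd:cd + w] = scaled[rs:rs + h, cs:cs + w]
    if dy or dx:
        shifted = np.full_like(out, img.min())
        src_r = slice(max(0, -dy), min(rows, rows - dy))
        dst_r = slice(max(0, dy), min(rows, rows + dy))
        src_c = slice(max(0, -dx), min(cols, cols - dx))
        dst_c = slice(max(0, dx), min(cols, cols + dx))
        shifted[dst_r, dst_c] = out[src_r, src_c]
        out = shifted
    return out


def curate_dataset(intervals: list[AnnotatedInterval], stacks: dict[str, SliceStack],
                   per_class_target: int = 960, cap: int = 10, seed: int = 0,
                   side: int = 256, max_shift_px: int = 12,
                   scale_range: tuple[float, float] = (0.9, 1.1)) -> CuratedDataset:
    """Assemble a laterality-balanced, class-balanced labelled image set.

    Per patient and label, up to ``cap`` evenly spaced slices are taken from
    the annotated interval; every image is also included horizontally
    flipped (laterality balance by construction).  Classes below
    ``per_class_target`` are topped up with augmented copies; classes above
    it are evenly subsampled, so all 9 class counts come out equal.
    Provenance (patient, slice, transform) is recorded per image.
    """
    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    rows: list[dict] = []
    for iv in intervals:
        if iv.patient_id not in stacks:
            raise CurationError(f"no stack for patient {iv.patient_id!r}")
        stack = stacks[iv.patient_id]
        for idx in select_even_interval(iv.start_slice, iv.end_slice, cap):
            if not 0 <= idx < len(stack):
                raise CurationError(
                    f"interval slice {idx} outside stack of patient {iv.patient_id!r}")
            img, _ = resize_to_model_input(stack.slices[idx], side=side)
            for tfm, arr in (("orig", img), ("flip", img[:, ::-1].copy())):
                images.append(arr.astype(np.float32))
                labels.append(iv.label)
                rows.append({"patient_id": iv.patient_id, "label": iv.label,
                             "slice_index": idx, "transform": tfm})

    labels_arr = np.asarray(labels)
    counts = {k: int((labels_arr == k).sum()) for k in range(N_CLASSES)}
    present = [k for k in range(N_CLASSES) if counts[k] > 0]
    for k in range(N_CLASSES):
        if counts[k] == 0:
            raise CurationError(f"label {k} has no images in any annotated interval")

    out_images: list[np.ndarray] = []
    out_labels: list[int] = []
    out_rows: list[dict] = []
    for k in present:
        idxs = np.flatnonzero(labels_arr == k)
        if len(idxs) > per_class_target:
            keep = rng.choice(idxs, size=per_class_target, replace=False)
            keep = np.sort(keep)
        else:
            keep = idxs
        for i in keep:
            out_images.append(images[i])
            out_labels.append(k)
            out_rows.append(rows[i])
        deficit = per_class_target - len(keep)
        for _ in range(deficit):
            src = int(rng.choice(idxs))
            aug_seed = int(rng.integers(0, 2**31 - 1))
            out_images.append(augment_image(images[src], max_shift_px, scale_range,
                                            seed=aug_seed).astype(np.float32))
            out_labels.append(k)
            row = dict(rows[src])
            row["transform"] = f"{row['transform']}+aug{aug_seed}"
            out_rows.append(row)
    return CuratedDataset(images=np.stack(out_images), labels=np.asarray(out_labels),
                          manifest=pd.DataFrame(out_rows))


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

_EXTRACTORS: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_extractor(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register an extractor: 2D image -> fixed-length 1D feature vector."""
    _EXTRACTORS[name] = fn


def available_extractors() -> list[str]:
    return sorted(_EXTRACTORS)


def _grid_hog_extractor(image: np.ndarray) -> np.ndarray:
    """Default offline descriptor: 16x16 mean-intensity grid (256 values,
    scaled to [0, 1]) concatenated with an 8-orientation HOG over 32 px
    cells.  Deterministic and needs no downloaded weights."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    grid = _sk_resize(norm, (16, 16), order=1, preserve_range=True,
                      anti_aliasing=True).ravel()
    hog_vec = hog(norm, orientations=8, pixels_per_cell=(32, 32),
                  cells_per_block=(1, 1), feature_vector=True)
    return np.concatenate([grid, hog_vec])


register_extractor("grid_hog", _grid_hog_extractor)


def extract_features(image: np.ndarray, extractor: str = "grid_hog") -> FeatureVector:
    """Extract a deterministic fixed-length feature vector from one image."""
    if extractor not in _EXTRACTORS:
        raise ConfigurationError(
            f"unknown extractor {extractor!r}; available: {available_extractors()}")
    values = np.asarray(_EXTRACTORS[extractor](np.asarray(image, dtype=float)))
    return FeatureVector(values=values, extractor_id=extractor)


def extract_feature_matrix(images: np.ndarray, extractor: str = "grid_hog") -> np.ndarray:
    return np.stack([extract_features(img, extractor).values for img in images])


# ---------------------------------------------------------------------------
# Boosted classifier
# ---------------------------------------------------------------------------

DEFAULT_XGB_PARAMS = {
    "max_depth": 4,
    "eta": 0.3,
    "subsample": 1.0,
    "tree_method": "hist",
    "nthread": 1,
}
DEFAULT_N_ROUNDS = 60


@dataclass
class ClassifierModel:
    """A fitted gradient-boosted landmark classifier plus its extractor id.

    Probabilities are always reported on the full 9-class simplex; classes
    absent from training get probability 0.
    """

    booster: "xgb.Booster | None" = None
    classes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    extractor_id: str = "grid_hog"

    @property
    def fitted(self) -> bool:
        return self.booster is not None and len(self.classes) >= 2

    def predict_proba_matrix(self, features: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("classifier model is not fitted")
        dm = xgb.DMatrix(np.asarray(features, dtype=np.float32))
        raw = np.atleast_2d(self.booster.predict(dm))
        out = np.zeros((raw.shape[0], N_CLASSES))
        out[:, self.classes] = raw
        return out

    def save(self, path: str | Path) -> Path:
        if not self.fitted:
            raise StateError("cannot save an unfitted model")
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(path))
        meta = {"classes": self.classes.tolist(), "extractor_id": self.extractor_id}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(str(path))
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(booster=booster, classes=np.asarray(meta["classes"], dtype=int),
                   extractor_id=meta["extractor_id"])


def fit_classifier(features: np.ndarray, labels: np.ndarray,
                   params: dict | None = None, seed: int = 0,
                   extractor_id: str = "grid_hog",
                   n_rounds: int = DEFAULT_N_ROUNDS) -> ClassifierModel:
    """Fit the 9-class gradient-boosted ensemble on feature vectors."""
    features = np.asarray(features, dtype=np.float32)
    labels = np.asarray(labels)
    if features.ndim != 2 or len(features) != len(labels):
        raise InputError("features must be (n, d) with one label per row")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise TrainingError("training needs at least 2 distinct classes")
    if classes.min() < 0 or classes.max() >= N_CLASSES:
        raise TrainingError("labels must be class ids 0-8")
    encoded = np.searchsorted(classes, labels)
    xgb_params = dict(DEFAULT_XGB_PARAMS)
    xgb_params.update(params or {})
    xgb_params.update({"objective": "multi:softprob", "num_class": len(classes),
                       "seed": seed})
    dm = xgb.DMatrix(features, label=encoded)
    booster = xgb.train(xgb_params, dm, num_boost_round=n_rounds)
    return ClassifierModel(booster=booster, classes=classes, extractor_id=extractor_id)


def predict_probabilities(model: ClassifierModel, image: np.ndarray,
                          extractor: str | None = None) -> np.ndarray:
    """Length-9 class-probability simplex vector for one model-input image."""
    feats = extract_features(image, extractor or model.extractor_id).values
    return model.predict_proba_matrix(feats[None, :])[0]


def retrieve_landmark_slices(model: ClassifierModel, stack: SliceStack,
                             targets: list[int] | None = None,
                             prob_floor: float = 0.2,
                             side: int = 256) -> dict[int, RetrievedSlice]:
    """Linear scan of per-slice probability arrays for each target label.

    Returns, per target, the stack index with the highest probability for
    that label (ties broken by the lowest index), the probability itself,
    and a low-confidence flag when the maximum falls below ``prob_floor``.
    """
    if targets is None:
        targets = sorted(TARGET_LABELS.values())
    if len(stack) == 0:
        raise InputError("stack is empty")
    feats = np.stack([
        extract_features(resize_to_model_input(sl, side=side)[0], model.extractor_id).values
        for sl in stack.slices
    ])
    probs = model.predict_proba_matrix(feats)  # (n_slices, 9)
    out: dict[int, RetrievedSlice] = {}
    for label in targets:
        col = probs[:, label]
        idx = int(np.argmax(col))  # np.argmax returns the first (lowest) maximizer
        p = float(col[idx])
        out[label] = RetrievedSlice(index=idx, probability=p, low_confidence=p < prob_floor)
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_classifier(predicted, true, average: str = "weighted") -> ClassifierMetrics:
    """Accuracy, averaged precision/recall/F1/Jaccard, Hamming loss and the
    9x9 confusion matrix for single-label multiclass predictions.

    ``average`` selects class-frequency-weighted (default) or macro
    averaging for the per-class metrics.
    """
    y_pred = np.asarray(predicted)
    y_true = np.asarray(true)
    if y_pred.shape != y_true.shape:
        raise InputError(f"length mismatch: {y_pred.shape} vs {y_true.shape}")
    if average not in ("weighted", "macro"):
        raise ParameterError("average must be 'weighted' or 'macro'")
    accuracy = float(np.mean(y_pred == y_true))
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average=average, zero_division=0)
    jaccard = jaccard_score(y_true, y_pred, average=average, zero_division=0)
    hamming = float(_sk_hamming(y_true, y_pred))
    confusion = confusion_matrix(y_true, y_pred, labels=np.arange(N_CLASSES))
    return ClassifierMetrics(accuracy=accuracy, precision=float(precision),
                             recall=float(recall), f1=float(f1), jaccard=float(jaccard),
                             hamming_loss=hamming, confusion=confusion, average=average)
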