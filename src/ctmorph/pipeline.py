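"""End-to-end orchestration: preprocess -> classify -> segment -> measure.

``run_pipeline`` composes the individually tested stage operations on one
slice stack and records per-stage wall time in the report.  A landmark that
cannot be retrieved or segmented degrades to an explicit absence flag on
the affected measurements; it never aborts the remaining ones.

``compare_to_reference`` reproduces the pipeline-versus-manual comparison
table: per measurement, paired means, mean absolute error, and a paired
two-sided location test (t-test by default, Wilcoxon signed-rank on
request).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, PairingError
from .imaging_io import MEASUREMENT_FIELDS, SliceStack, resample_isotropic
from .landmark_classifier import (
    TARGET_LABELS,
    ClassifierModel,
    retrieve_landmark_slices,
)
from .mask_segmentation import segment_slice
from .morphometry import MeasurementReport, measure_all

__all__ = ["PipelineConfig", "run_pipeline", "compare_to_reference", "ComparisonTable"]

_LABEL_NAMES = {v: k for k, v in TARGET_LABELS.items()}


@dataclass
class PipelineConfig:
    """Run-time configuration for one pipeline execution."""

    model_path: str | None = None
    extractor: str = "grid_hog"
    backend: str = "baseline"
    targets: tuple[int, ...] = (2, 4, 6, 8)
    prob_floor: float = 0.2
    min_depth_mm: float = 1.0
    seed: int = 0
    model_input_side: int = 256

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Parse a flat ``key = value`` text config; CLI flags override."""
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"config line {lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise ConfigurationError(f"config line {lineno}: unknown key {key!r}")
            values[key] = val
        if "targets" in values and isinstance(values["targets"], str):
            values["targets"] = tuple(int(t) for t in values["targets"].split(","))
        for key in ("prob_floor", "min_depth_mm"):
            if key in values:
                values[key] = float(values[key])
        for key in ("seed", "model_input_side"):
            if key in values:
                values[key] = int(values[key])
        values.update(overrides)
        return cls(**values)


def run_pipeline(stack: SliceStack, model: ClassifierModel,
                 config: PipelineConfig | None = None) -> MeasurementReport:
    """Run preprocess -> retrieve -> segment -> measure on one stack.

    Returns a :class:`MeasurementReport` with the five measurements (or
    explicit absence reasons), the landmark points, the retrieved slice
    indices, and the four stage wall times.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    iso = resample_isotropic(stack)
    timings["preprocess_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    retrieved = retrieve_landmark_slices(model, iso, targets=list(config.targets),
                                         prob_floor=config.prob_floor,
                                         side=config.model_input_side)
    timings["classify_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    masks = {}
    retrieval_notes: dict[str, str] = {}
    for label, hit in retrieved.items():
        name = _LABEL_NAMES.get(label, str(label))
        if hit.low_confidence:
            retrieval_notes[name] = (
                f"landmark not found: best probability {hit.probability:.3f} "
                f"below floor {config.prob_floor}")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = segment_slice(iso.slices[hit.index], backend=config.backend,
                                 spacing=iso.spacing, source_slice_index=hit.index)
        if not mask.grid.any():
            retrieval_notes[name] = "segmentation produced an empty mask"
            continue
        masks[label] = mask
    timings["segment_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = measure_all(masks, laterality=stack.laterality,
                         min_depth_mm=config.min_depth_mm, patient_id=stack.patient_id)
    timings["measure_s"] = time.perf_counter() - t0

    # annotate absences caused upstream of measurement
    for name, units in MEASUREMENT_FIELDS:
        src = MeasurementReport._SLICE_KEYS[name]
        if src in retrieval_notes and name in report.absent:
            report.absent[name] = retrieval_notes[src]
    report.timings_s = timings
    report.seed = config.seed
    for label, hit in retrieved.items():
        name = _LABEL_NAMES.get(label, str(label))
        report.source_slices.setdefault(name, hit.index)
    return report


# ---------------------------------------------------------------------------
# Pipeline-versus-reference comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """Per-measurement paired comparison of pipeline and reference reports."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def compare_to_reference(pipeline_reports: list[MeasurementReport],
                         reference_reports: list[MeasurementReport],
                         test: str = "ttest") -> ComparisonTable:
    """Build the pipeline-versus-manual comparison table.

    Reports are paired by patient id (n >= 2 pairs required).  For every
    measurement present in both report sets: pipeline mean +- sd, reference
    mean +- sd, mean absolute error +- sd, and the p-value of a paired
    two-sided location test — paired t-test by default, Wilcoxon signed-rank
    with ``test='wilcoxon'``.
    """
    if test not in ("ttest", "wilcoxon"):
        raise ConfigurationError("test must be 'ttest' or 'wilcoxon'")
    pipe = {r.patient_id: r for r in pipeline_reports}
    ref = {r.patient_id: r for r in reference_reports}
    unpaired = sorted(set(pipe) ^ set(ref))
    if unpaired:
        raise PairingError(f"unpaired patient ids: {unpaired}")
    ids = sorted(pipe)
    if len(ids) < 2:
        raise InputError("need at least 2 paired reports")

    rows = []
    for name, units in MEASUREMENT_FIELDS:
        a = np.array([getattr(pipe[i], name) for i in ids], dtype=float)
        b = np.array([getattr(ref[i], name) for i in ids], dtype=float)
        keep = np.isfinite(a) & np.isfinite(b)
        if keep.sum() < 2:
            continue
        a, b = a[keep], b[keep]
        err = np.abs(a - b)
        if np.allclose(a, b):
            p = 1.0
        elif test == "ttest":
            p = float(stats.ttest_rel(a, b).pvalue)
        else:
            p = float(stats.wilcoxon(a, b).pvalue)
        rows.append({
            "measurement": name, "units": units, "n": int(keep.sum()),
            "pipeline_mean": a.mean(), "pipeline_sd": a.std(ddof=1),
            "reference_mean": b.mean(), "reference_sd": b.std(ddof=1),
            "mean_abs_error": err.mean(), "abs_error_sd": err.std(ddof=1),
            "p_value": p, "test": test,
        })
    return ComparisonTable(table=pd.DataFrame(rows))
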