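"""Shared fixtures: small phantom cohorts and a trained slice classifier.

Everything is generated programmatically and deterministically; no image
data ships with the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctmorph import phantom
from ctmorph.landmark_classifier import (
    AnnotatedInterval,
    curate_dataset,
    extract_feature_matrix,
    fit_classifier,
)


def make_cohort(n_patients: int, seed: int, n_slices: int = 27):
    """Generate a phantom patient cohort with randomized morphometrics.

    Returns (stacks, intervals, truths) keyed/labelled by patient id.
    Parameter ranges follow the normal clinical ranges the measurements are
    validated against (anteversion 12-20, sulcus around 135-145, ...) with
    some spread beyond them.
    """
    rng = np.random.default_rng(seed)
    stacks, truths = {}, {}
    intervals: list[AnnotatedInterval] = []
    for i in range(n_patients):
        pid = f"p{i:03d}"
        stack, labels, truth = phantom.make_patient_stack(
            version_deg=float(rng.uniform(-10.0, 30.0)),
            anteversion_deg=float(rng.uniform(5.0, 28.0)),
            sulcus_deg=float(rng.uniform(125.0, 155.0)),
            pca_deg=float(rng.uniform(0.0, 12.0)),
            tttg_mm=float(rng.uniform(2.0, 20.0)),
            n_slices=n_slices,
            seed=int(rng.integers(0, 2**31 - 1)),
            laterality="left" if i % 2 else "right",
            patient_id=pid,
        )
        stacks[pid] = stack
        truths[pid] = (labels, truth)
        lab = np.asarray(labels)
        for k in range(9):
            idx = np.flatnonzero(lab == k)
            intervals.append(AnnotatedInterval(pid, k, int(idx.min()), int(idx.max())))
    return stacks, intervals, truths


def train_on_cohort(stacks, intervals, patient_ids, per_class_target: int, seed: int):
    """Curate + extract + fit on the given patient subset."""
    subset = [iv for iv in intervals if iv.patient_id in patient_ids]
    sub_stacks = {pid: stacks[pid] for pid in patient_ids}
    ds = curate_dataset(subset, sub_stacks, per_class_target=per_class_target, seed=seed)
    feats = extract_feature_matrix(ds.images)
    model = fit_classifier(feats, ds.labels, seed=seed)
    return model, ds


@pytest.fixture(scope="session")
def small_cohort():
    """6 phantom patients for module-level classifier/pipeline tests."""
    return make_cohort(6, seed=20260923)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    stacks, intervals, _ = small_cohort
    model, _ = train_on_cohort(stacks, intervals, sorted(stacks), per_class_target=40, seed=11)
    return model
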