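"""Slice-selection, curation, feature extraction, boosted classifier and
retrieval behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctmorph.errors import (
    ConfigurationError,
    CurationError,
    InputError,
    IntervalError,
    ParameterError,
    StateError,
    TrainingError,
)
from ctmorph.imaging_io import PixelSpacing, SliceStack
from ctmorph.landmark_classifier import (
    N_CLASSES,
    AnnotatedInterval,
    ClassifierModel,
    RetrievedSlice,
    augment_image,
    curate_dataset,
    evaluate_classifier,
    extract_features,
    fit_classifier,
    predict_probabilities,
    retrieve_landmark_slices,
    select_even_interval,
)


class TestSelectEvenInterval:
    def test_worked_example_0_to_50(self):
        assert select_even_interval(0, 50, 10) == [0, 5, 10, 15, 20, 25, 30, 35, 40, 45]

    def test_singleton(self):
        assert select_even_interval(3, 3, 10) == [3]

    def test_cap_not_binding(self):
        assert select_even_interval(0, 7, 10) == [0, 1, 2, 3, 4, 5, 6, 7]

    def test_invalid_interval(self):
        with pytest.raises(IntervalError):
            select_even_interval(5, 2)

    @given(start=st.integers(0, 200), length=st.integers(0, 300), cap=st.integers(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_properties(self, start, length, cap):
        out = select_even_interval(start, start + length, cap)
        assert len(out) == min(length + 1, cap)
        assert all(start <= i <= start + length for i in out)
        assert out == sorted(set(out))


class TestAugmentImage:
    def test_identity(self):
        img = np.random.default_rng(0).normal(size=(64, 64))
        out = augment_image(img, max_shift_px=0, scale_range=(1.0, 1.0), seed=0)
        assert np.array_equal(out, img)

    def test_dims_preserved_and_deterministic(self):
        img = np.random.default_rng(1).normal(size=(48, 80))
        a = augment_image(img, max_shift_px=7, scale_range=(0.8, 1.2), seed=5)
        b = augment_image(img, max_shift_px=7, scale_range=(0.8, 1.2), seed=5)
        assert a.shape == img.shape
        assert np.array_equal(a, b)

    def test_degenerate_scale_range(self):
        with pytest.raises(ParameterError):
            augment_image(np.zeros((8, 8)), scale_range=(1.5, 0.5))
        with pytest.raises(ParameterError):
            augment_image(np.zeros((8, 8)), scale_range=(0.2, 1.0))


class TestCurateDataset:
    def test_balanced_counts_and_flip_doubling(self, small_cohort):
        stacks, intervals, _ = small_cohort
        pid = sorted(stacks)[0]
        ds = curate_dataset([iv for iv in intervals if iv.patient_id == pid],
                            {pid: stacks[pid]}, per_class_target=12, seed=0)
        counts = np.bincount(ds.labels, minlength=N_CLASSES)
        assert (counts == 12).all()
        tfm = ds.manifest["transform"]
        originals = ds.manifest[~tfm.str.contains("aug")]
        assert (originals["transform"] == "orig").sum() == (originals["transform"] == "flip").sum()
        # per-patient-per-label originals capped at cap, doubled by flipping
        per_label = originals.groupby("label").size()
        assert (per_label <= 10 * 2).all()

    def test_missing_label_raises(self, small_cohort):
        stacks, intervals, _ = small_cohort
        pid = sorted(stacks)[0]
        partial = [iv for iv in intervals if iv.patient_id == pid and iv.label != 4]
        with pytest.raises(CurationError, match="4"):
            curate_dataset(partial, {pid: stacks[pid]}, per_class_target=6, seed=0)


class TestFeatures:
    def test_deterministic_fixed_length(self):
        rng = np.random.default_rng(2)
        img_a, img_b = rng.normal(size=(2, 256, 256))
        fa1 = extract_features(img_a)
        fa2 = extract_features(img_a)
        fb = extract_features(img_b)
        assert np.array_equal(fa1.values, fa2.values)
        assert fa1.values.shape == fb.values.shape
        assert np.isfinite(fa1.values).all()

    def test_unknown_extractor(self):
        with pytest.raises(ConfigurationError):
            extract_features(np.zeros((256, 256)), extractor="cnn-nonexistent")

    def test_linear_probe_separates_phantom_classes(self, small_cohort):
        """The default descriptor linearly separates the 9 slice classes."""
        from sklearn.linear_model import LogisticRegression

        from ctmorph.imaging_io import resize_to_model_input
        from ctmorph.landmark_classifier import extract_feature_matrix

        stacks, _, truths = small_cohort
        ids = sorted(stacks)
        X, y, groups = [], [], []
        for pid in ids:
            labels, _ = truths[pid]
            imgs = np.stack([resize_to_model_input(sl)[0] for sl in stacks[pid].slices])
            X.append(extract_feature_matrix(imgs))
            y.extend(labels)
            groups.extend([pid] * len(labels))
        X = np.vstack(X)
        y = np.asarray(y)
        groups = np.asarray(groups)
        train = np.isin(groups, ids[:4])
        probe = LogisticRegression(max_iter=2000).fit(X[train], y[train])
        assert probe.score(X[~train], y[~train]) >= 0.9


class TestFitPredict:
    def toy_set(self):
        a = np.zeros(16)
        b = np.ones(16)
        X = np.vstack([a] * 10 + [b] * 10)
        y = np.array([0] * 10 + [5] * 10)
        return X, y

    def test_separable_toy_training_accuracy(self):
        X, y = self.toy_set()
        model = fit_classifier(X, y, seed=0)
        probs = model.predict_proba_matrix(X)
        assert (probs.argmax(axis=1) == y).all()
        # probabilities live on the full 9-class simplex
        assert probs.shape == (20, N_CLASSES)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            fit_classifier(np.zeros((5, 3)), np.zeros(5, dtype=int))

    def test_unfitted_model_state_error(self):
        with pytest.raises(StateError):
            ClassifierModel().predict_proba_matrix(np.zeros((1, 3)))

    def test_persistence_round_trip(self, tmp_path):
        X, y = self.toy_set()
        model = fit_classifier(X, y, seed=1)
        path = model.save(tmp_path / "clf.json")
        back = ClassifierModel.load(path)
        assert np.array_equal(back.classes, model.classes)
        assert np.allclose(back.predict_proba_matrix(X), model.predict_proba_matrix(X))

    def test_predict_probabilities_on_image(self, small_model, small_cohort):
        stacks, _, truths = small_cohort
        pid = sorted(stacks)[0]
        from ctmorph.imaging_io import resize_to_model_input

        img, _ = resize_to_model_input(stacks[pid].slices[0])
        probs = predict_probabilities(small_model, img)
        assert probs.shape == (N_CLASSES,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)


class _FakeModel(ClassifierModel):
    """Duck-typed model returning a preset probability matrix."""

    def __init__(self, matrix):
        super().__init__()
        self._matrix = np.asarray(matrix)
        self.extractor_id = "grid_hog"

    def predict_proba_matrix(self, features):
        return self._matrix[: len(features)]


class TestRetrieve:
    def test_argmax_and_tie_rule(self):
        probs = np.zeros((4, N_CLASSES))
        probs[:, 0] = 1.0
        probs[1, 2] = probs[3, 2] = 0.6  # tie: slice 1 and 3
        probs[2, 4] = 0.9
        probs /= probs.sum(axis=1, keepdims=True)
        stack = SliceStack(np.zeros((4, 32, 32)), PixelSpacing(1, 1), "right", "t")
        out = retrieve_landmark_slices(_FakeModel(probs), stack, targets=[2, 4])
        assert out[2].index == 1  # lowest index wins the tie
        assert out[4].index == 2
        assert not out[4].low_confidence

    def test_low_confidence_flag(self):
        probs = np.full((3, N_CLASSES), 1.0 / N_CLASSES)
        stack = SliceStack(np.zeros((3, 32, 32)), PixelSpacing(1, 1), "right", "t")
        out = retrieve_landmark_slices(_FakeModel(probs), stack, targets=[6])
        assert out[6].low_confidence

    def test_append_invariance(self):
        """Appending slices with lower target probability keeps the result."""
        probs = np.zeros((5, N_CLASSES))
        probs[:, 0] = 1.0
        probs[2, 8] = 0.7
        probs[4, 8] = 0.3  # appended, below current max
        probs /= probs.sum(axis=1, keepdims=True)
        short = SliceStack(np.zeros((4, 32, 32)), PixelSpacing(1, 1), "right", "t")
        full = SliceStack(np.zeros((5, 32, 32)), PixelSpacing(1, 1), "right", "t")
        r_short = retrieve_landmark_slices(_FakeModel(probs), short, targets=[8])
        r_full = retrieve_landmark_slices(_FakeModel(probs), full, targets=[8])
        assert r_short[8].index == r_full[8].index == 2

    def test_retrieval_hits_landmark_intervals(self, small_model, small_cohort):
        stacks, _, truths = small_cohort
        hits = total = 0
        for pid in sorted(stacks)[4:]:
            labels, truth = truths[pid]
            out = retrieve_landmark_slices(small_model, stacks[pid])
            for label, hit in out.items():
                lo = labels.index(label)
                hi = len(labels) - 1 - labels[::-1].index(label)
                center = truth.landmark_slice_index[label]
                total += 1
                hits += (lo <= hit.index <= hi) and abs(hit.index - center) <= 2
        assert hits == total


class TestEvaluateClassifier:
    def test_perfect_predictions(self):
        y = np.arange(N_CLASSES)
        m = evaluate_classifier(y, y)
        assert m.accuracy == 1.0 and m.hamming_loss == 0.0
        assert m.precision == m.recall == m.f1 == m.jaccard == 1.0
        assert np.array_equal(m.confusion, np.eye(N_CLASSES, dtype=int))

    def test_per_class_recall_32_of_40(self):
        """A class with 32 of 40 correct instances has per-class recall 0.80."""
        y_true = np.array([4] * 40)
        y_pred = np.array([4] * 32 + [3] * 1 + [5] * 7)
        m = evaluate_classifier(y_pred, y_true)
        recall_class4 = m.confusion[4, 4] / m.confusion[4].sum()
        assert recall_class4 == pytest.approx(0.80)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            evaluate_classifier([0, 1], [0])

    @given(st.lists(st.tuples(st.integers(0, 8), st.integers(0, 8)),
                    min_size=1, max_size=200))
    @settings(max_examples=60, deadline=None)
    def test_hamming_and_confusion_against_brute_force(self, pairs):
        y_pred = np.array([p for p, _ in pairs])
        y_true = np.array([t for _, t in pairs])
        m = evaluate_classifier(y_pred, y_true)
        # brute-force confusion counting
        brute = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
        for p, t in pairs:
            brute[t, p] += 1
        assert np.array_equal(m.confusion, brute)
        assert m.hamming_loss == pytest.approx(1.0 - m.accuracy, abs=1e-12)
        assert m.confusion.sum() == len(pairs)
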