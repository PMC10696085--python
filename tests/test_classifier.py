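"""Patch classifier: normalisation, threshold selection, metrics, training."""

import numpy as np
import pytest

from musemap import (DecisionThreshold, PatchClassifier, compute_metrics,
                     normalize_clf, select_threshold)
from musemap.classifier import _f1_from_counts


class TestNormalization:
    def test_scales_by_patch_maximum(self):
        patch = np.zeros((4, 4, 3), np.float32)
        patch[0, 0, 0] = 200.0
        out = normalize_clf(patch)
        assert out.max() == pytest.approx(1.0)
        assert out[0, 0, 0] == pytest.approx(1.0)

    def test_all_zero_patch_stays_zero(self):
        out = normalize_clf(np.zeros((8, 8, 3)))
        assert not np.any(out)

    def test_constant_patch_becomes_all_ones(self):
        out = normalize_clf(np.full((8, 8, 3), 37.0))
        assert np.allclose(out, 1.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            normalize_clf(np.array([-1.0, 3.0]))


def _brute_force_best_f1(scores, labels):
    best = -1.0
    for t in np.concatenate([[0.0, 1.0], scores, (scores + 1e-9)]):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        best = max(best, _f1_from_counts(tp, fp, fn))
    return best


class TestThresholdSelection:
    def test_separable_scores_give_midpoint(self):
        t = select_threshold(np.array([0.1, 0.2, 0.8, 0.9]),
                             np.array([0, 0, 1, 1]))
        assert t.value == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_attains_brute_force_optimum(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(size=30).round(2)
        labels = (rng.uniform(size=30) > 0.4).astype(int)
        t = select_threshold(scores, labels)
        m = compute_metrics(scores, labels, t)
        assert m.f1 == pytest.approx(_brute_force_best_f1(scores, labels),
                                     abs=1e-9)

    def test_inverted_scores_still_optimal(self):
        scores = np.array([0.4, 0.6])
        labels = np.array([1, 0])
        t = select_threshold(scores, labels)
        m = compute_metrics(scores, labels, t)
        assert m.f1 == pytest.approx(_brute_force_best_f1(scores, labels))

    def test_all_equal_scores_predict_everything_positive(self):
        # any threshold <= the common score keeps F1 > 0; t=1 would zero recall
        t = select_threshold(np.full(6, 0.5), np.array([1, 1, 1, 0, 0, 1]))
        m = compute_metrics(np.full(6, 0.5), np.array([1, 1, 1, 0, 0, 1]), t)
        assert m.fn == 0 and m.tp == 4

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestMetrics:
    def test_perfect_scores(self):
        m = compute_metrics(np.array([0.9, 0.8, 0.1, 0.2]),
                            np.array([1, 1, 0, 0]), DecisionThreshold(0.5))
        assert (m.accuracy, m.f1, m.auc) == (1.0, 1.0, 1.0)

    def test_hand_enumerated_confusion_and_auc(self):
        m = compute_metrics(np.array([0.9, 0.4, 0.6, 0.1]),
                            np.array([1, 1, 0, 0]), DecisionThreshold(0.5))
        assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 1, 1)
        assert m.accuracy == pytest.approx(0.5)
        assert m.f1 == pytest.approx(0.5)
        assert m.auc == pytest.approx(0.75)  # 3 of 4 rank pairs correct

    def test_random_scores_give_null_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=2000)
        labels = (rng.uniform(size=2000) > 0.5).astype(int)
        m = compute_metrics(scores, labels, DecisionThreshold(0.5))
        assert m.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0.01, 0.99, size=200)
        labels = (rng.uniform(size=200) > 0.5).astype(int)
        t = DecisionThreshold(0.5)
        a1 = compute_metrics(scores, labels, t).auc
        a2 = compute_metrics(scores ** 3, labels, t).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0.5]), np.array([1, 0]),
                            DecisionThreshold(0.5))


def _separable_patches(n=60, size=32, seed=0):
    """High-contrast speckle positives vs flat negatives.

    Because patches are max-normalised, the classes are made to differ in
    texture (post-normalisation mean ~0.5 vs ~1.0), not absolute brightness.
    """
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    x = np.empty((n, size, size, 3), np.float32)
    for i in range(n):
        if y[i]:
            x[i] = rng.choice([0.0, 255.0], size=(size, size, 3))
        else:
            x[i] = np.clip(128.0 + rng.normal(0, 10, (size, size, 3)), 0, 255)
    return x, y


@pytest.fixture(scope="module")
def fitted():
    x, y = _separable_patches()
    xv, yv = _separable_patches(n=30, seed=1)
    clf = PatchClassifier(phase1_epochs=2, phase2_epochs=3,
                          random_state=0).fit(x, y, X_val=xv, y_val=yv)
    return clf, xv, yv


class TestTraining:
    def test_separable_data_reaches_perfect_validation(self, fitted):
        clf, _, _ = fitted
        assert clf.best_val_accuracy_ == 1.0

    def test_checkpoint_is_best_epoch(self, fitted):
        clf, xv, yv = fitted
        val_accs = [h["val_accuracy"] for h in clf.history_]
        assert clf.best_val_accuracy_ == max(val_accs)
        assert clf.best_epoch_ == int(np.argmax(val_accs))  # earliest on ties

    def test_reload_reproduces_validation_accuracy(self, fitted, tmp_path):
        clf, xv, yv = fitted
        clf.save(tmp_path / "clf.npz")
        clone = PatchClassifier.from_file(tmp_path / "clf.npz")
        acc = np.mean((clone.decision_scores(xv) >= 0.5) == (yv == 1))
        assert acc == clf.best_val_accuracy_
        assert clone.threshold_.value == clf.threshold_.value

    def test_seeded_runs_are_identical(self):
        x, y = _separable_patches(n=20)
        h1 = PatchClassifier(phase1_epochs=1, phase2_epochs=1,
                             random_state=5).fit(x, y).history_
        h2 = PatchClassifier(phase1_epochs=1, phase2_epochs=1,
                             random_state=5).fit(x, y).history_
        assert h1 == h2

    def test_two_phase_schedule_recorded(self, fitted):
        clf, _, _ = fitted
        phases = [h["phase"] for h in clf.history_]
        assert phases == [1.0, 1.0, 2.0, 2.0, 2.0]

    def test_single_class_training_rejected(self):
        x, _ = _separable_patches(n=10)
        with pytest.raises(ValueError):
            PatchClassifier(phase1_epochs=1, phase2_epochs=0).fit(
                x, np.ones(10, int))
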