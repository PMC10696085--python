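"""1-pixel diagnosis rule and accuracy accounting."""

import numpy as np
import pytest

from musemap import (DecisionThreshold, DiagnosisRecord, SyntheticImage,
                     Table1Accounting, WindowConfig, VotingConfig,
                     diagnose_image, run_condition_experiment, score_diagnoses)
from musemap.evaluation import (REFERENCE_FFPE_PATCH_SPLIT, REFERENCE_TABLE1,
                                REFERENCE_TEST_IMAGES, round1)


class TestDiagnoseImage:
    def test_clean_map_is_negative(self):
        assert diagnose_image(np.zeros((10, 10), np.uint8)) == "negative"

    def test_single_positive_cell_is_positive(self):
        grid = np.zeros((10, 10), np.uint8)
        grid[3, 7] = 1
        assert diagnose_image(grid) == "positive"

    def test_all_positive_is_positive(self):
        assert diagnose_image(np.ones((5, 5), np.uint8)) == "positive"

    def test_monotone_under_added_positives(self):
        rng = np.random.default_rng(0)
        grid = (rng.uniform(size=(8, 8)) < 0.1).astype(np.uint8)
        verdict = diagnose_image(grid)
        grid2 = grid.copy()
        grid2[0, 0] = 1
        assert not (verdict == "positive"
                    and diagnose_image(grid2) == "negative")

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            diagnose_image(np.zeros((0, 0), np.uint8))


def _records(n_correct_neg, n_neg, n_correct_pos, n_pos):
    recs = []
    for i in range(n_neg):
        recs.append(DiagnosisRecord(f"n{i}", "negative",
                                    "negative" if i < n_correct_neg else "positive"))
    for i in range(n_pos):
        recs.append(DiagnosisRecord(f"p{i}", "positive",
                                    "positive" if i < n_correct_pos else "negative"))
    return recs


class TestAccounting:
    def test_reference_counts_reproduce_published_percentages(self):
        acc_with = Table1Accounting.from_counts(
            REFERENCE_TABLE1["with_translation"])
        acc_without = Table1Accounting.from_counts(
            REFERENCE_TABLE1["without_translation"])
        r_with, r_without = acc_with.rounded(), acc_without.rounded()
        assert r_with["InceptionV3"] == 86.8
        assert r_with["DenseNet-121"] == 81.3
        assert r_with["EfficientNetB4"] == 85.7
        assert r_with["class_average_negative"] == 82.6
        assert r_with["class_average_positive"] == 86.7
        assert r_with["model_average"] == 84.6
        assert r_without["InceptionV3"] == 67.0
        assert r_without["DenseNet-121"] == 62.6
        assert r_without["EfficientNetB4"] == 69.2
        assert r_without["class_average_negative"] == 53.6
        assert r_without["class_average_positive"] == 79.3
        assert r_without["model_average"] == 66.3
        assert round1(acc_with.model_average - acc_without.model_average) == 18.3

    def test_all_correct_toy_input(self):
        acc = score_diagnoses({"toy": _records(5, 5, 5, 5)})
        assert acc.rounded()["toy"] == 100.0

    def test_model_average_is_mean_of_model_accuracies(self):
        counts = {"m1": (30, 46, 31, 45), "m2": (20, 46, 37, 45),
                  "m3": (41, 46, 22, 45)}
        acc = Table1Accounting.from_counts(counts)
        expected = np.mean([100 * (c[0] + c[2]) / (c[1] + c[3])
                            for c in counts.values()])
        assert acc.model_average == pytest.approx(expected)

    def test_class_averages_pool_counts(self):
        counts = {"m1": (1, 4, 2, 6), "m2": (3, 4, 5, 6)}
        acc = Table1Accounting.from_counts(counts)
        assert acc.class_average_neg == pytest.approx(100 * 4 / 8)
        assert acc.class_average_pos == pytest.approx(100 * 7 / 12)

    def test_score_diagnoses_counts_records(self):
        acc = score_diagnoses({"m": _records(3, 4, 5, 6)})
        m = acc.models["m"]
        assert (m.correct_neg, m.total_neg, m.correct_pos, m.total_pos) \
            == (3, 4, 5, 6)

    def test_all_negative_predictor_splits_classes(self):
        recs = [DiagnosisRecord(f"n{i}", "negative", "negative")
                for i in range(7)]
        recs += [DiagnosisRecord(f"p{i}", "positive", "negative")
                 for i in range(5)]
        acc = score_diagnoses({"m": recs})
        assert acc.class_average_neg == 100.0
        assert acc.class_average_pos == 0.0

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            score_diagnoses({"m": []})

    def test_rendered_table_contains_counts_and_averages(self):
        acc = Table1Accounting.from_counts(
            REFERENCE_TABLE1["with_translation"])
        text = acc.render("With translation")
        assert "39/46" in text and "86.8" in text and "84.6" in text


class TestReferenceBookkeeping:
    def test_patch_split_total(self):
        assert sum(REFERENCE_FFPE_PATCH_SPLIT.values()) == 27704

    def test_test_image_total(self):
        assert sum(REFERENCE_TEST_IMAGES.values()) == 91


class _MaskIntensityScorer:
    """Scores a window by mean intensity / 255 — exact for mask-coded pixels."""

    def decision_scores(self, windows):
        return np.asarray(windows).mean(axis=(1, 2, 3)) / 255.0


def _mask_coded_image(positive: bool, idx: int) -> SyntheticImage:
    mask = np.zeros((96, 96), np.uint8)
    if positive:
        mask[24:72, 24:72] = 1
    pixels = np.repeat((mask * 255.0)[:, :, None], 3, axis=2).astype(np.float32)
    return SyntheticImage(pixels=pixels, domain="unfixed",
                          label="positive" if positive else "negative",
                          mask=mask, image_id=f"coded-{idx}")


class TestConditionExperiment:
    def test_oracle_scorer_achieves_perfect_accuracy(self):
        images = [_mask_coded_image(True, 0), _mask_coded_image(True, 1),
                  _mask_coded_image(False, 2), _mask_coded_image(False, 3)]
        records, acc = run_condition_experiment(
            images, None, _MaskIntensityScorer(), DecisionThreshold(0.5),
            WindowConfig(32, 16, 16), VotingConfig(2, 0.95), "oracle")
        assert acc.rounded()["oracle"] == 100.0
        assert all(r.correct for r in records)

    def test_experiment_is_deterministic(self):
        images = [_mask_coded_image(True, 0), _mask_coded_image(False, 1)]
        args = (images, None, _MaskIntensityScorer(), DecisionThreshold(0.5),
                WindowConfig(32, 16, 16), VotingConfig(2, 0.95), "m")
        r1, a1 = run_condition_experiment(*args)
        r2, a2 = run_condition_experiment(*args)
        assert r1 == r2
        assert a1.rounded() == a2.rounded()
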