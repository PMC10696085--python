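"""Image-level diagnosis and accuracy accounting.

The whole-image verdict follows the 1-pixel rule: an image is called
metastasis-positive iff its voted map contains at least one positive cell.
A negative image is therefore correct only when its voted map is entirely
clean, and a positive image is correct as soon as any cell fires.

Accounting mirrors the reference study's summary table: per-model rows of
``correct/total`` for each class plus a percent accuracy, per-class pooled
averages (pooled correct / pooled total), and a per-condition average that
is the arithmetic mean of the per-model accuracies.  Percentages are
reported to one decimal, round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .classifier import DecisionThreshold, PatchClassifier
from .gan import TranslatorPair
from .mapping import WindowConfig, compute_label_map
from .synthetic import SyntheticImage
from .voting import VotedMap, VotingConfig, majority_vote

# Published reference accounting of the clinical MUSE lymph-node study
# (gastric-cancer lymph nodes, voting threshold 95%): per model,
# (correct_negative, total_negative, correct_positive, total_positive).
REFERENCE_TABLE1 = {
    "without_translation": {
        "InceptionV3": (38, 46, 23, 45),
        "DenseNet-121": (17, 46, 40, 45),
        "EfficientNetB4": (19, 46, 44, 45),
    },
    "with_translation": {
        "InceptionV3": (39, 46, 40, 45),
        "DenseNet-121": (33, 46, 41, 45),
        "EfficientNetB4": (42, 46, 36, 45),
    },
}

# FFPE patch dataset split sizes used to train the reference classifiers.
REFERENCE_FFPE_PATCH_SPLIT = {
    "train_positive": 10502, "train_negative": 9931,
    "val_positive": 1988, "val_negative": 1455,
    "test_positive": 1834, "test_negative": 1994,
}

# Whole-image test set of the reference study (unfixed lymph nodes).
REFERENCE_TEST_IMAGES = {"positive": 45, "negative": 46}


def round1(x: float) -> float:
    """One-decimal round-half-up, the table's reporting convention."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DiagnosisRecord:
    image_id: str
    true_label: str       # "positive" | "negative"
    predicted_label: str

    @property
    def correct(self) -> bool:
        return self.true_label == self.predicted_label


def diagnose_image(voted: VotedMap | np.ndarray) -> str:
    """1-pixel rule: positive iff any voted cell is positive."""
    grid = voted.grid if isinstance(voted, VotedMap) else np.asarray(voted)
    if grid.size == 0:
        raise ValueError("empty voted map")
    return "positive" if np.any(grid) else "negative"


@dataclass
class ModelAccounting:
    correct_neg: int
    total_neg: int
    correct_pos: int
    total_pos: int

    @property
    def accuracy(self) -> float:
        total = self.total_neg + self.total_pos
        if total == 0:
            raise ValueError("zero totals")
        return 100.0 * (self.correct_neg + self.correct_pos) / total


@dataclass
class Table1Accounting:
    """Per-model counts plus class-pooled and model-averaged accuracies."""

    models: dict[str, ModelAccounting]

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int, int, int]]
                    ) -> "Table1Accounting":
        return cls({name: ModelAccounting(*c) for name, c in counts.items()})

    @property
    def model_average(self) -> float:
        """Mean of the per-model accuracies (percent, unrounded)."""
        accs = [m.accuracy for m in self.models.values()]
        return float(np.mean(accs))

    @property
    def class_average_neg(self) -> float:
        correct = sum(m.correct_neg for m in self.models.values())
        total = sum(m.total_neg for m in self.models.values())
        if total == 0:
            raise ValueError("zero totals")
        return 100.0 * correct / total

    @property
    def class_average_pos(self) -> float:
        correct = sum(m.correct_pos for m in self.models.values())
        total = sum(m.total_pos for m in self.models.values())
        if total == 0:
            raise ValueError("zero totals")
        return 100.0 * correct / total

    def rounded(self) -> dict[str, float]:
        out = {name: round1(m.accuracy) for name, m in self.models.items()}
        out["class_average_negative"] = round1(self.class_average_neg)
        out["class_average_positive"] = round1(self.class_average_pos)
        out["model_average"] = round1(self.model_average)
        return out

    def render(self, title: str = "") -> str:
        lines = []
        if title:
            lines.append(title)
        lines.append(f"{'model':<16}{'met(-)':>10}{'met(+)':>10}{'accuracy':>10}")
        for name, m in self.models.items():
            lines.append(
                f"{name:<16}{f'{m.correct_neg}/{m.total_neg}':>10}"
                f"{f'{m.correct_pos}/{m.total_pos}':>10}"
                f"{round1(m.accuracy):>10.1f}")
        lines.append(
            f"{'Average (%)':<16}{round1(self.class_average_neg):>10.1f}"
            f"{round1(self.class_average_pos):>10.1f}"
            f"{round1(self.model_average):>10.1f}")
        return "\n".join(lines)


def score_diagnoses(records_by_model: dict[str, list[DiagnosisRecord]]
                    ) -> Table1Accounting:
    """Aggregate per-image diagnosis records into the accounting table."""
    counts: dict[str, tuple[int, int, int, int]] = {}
    for name, records in records_by_model.items():
        if not records:
            raise ValueError(f"no records for model {name!r}")
        cn = sum(1 for r in records if r.true_label == "negative" and r.correct)
        tn = sum(1 for r in records if r.true_label == "negative")
        cp = sum(1 for r in records if r.true_label == "positive" and r.correct)
        tp = sum(1 for r in records if r.true_label == "positive")
        if tn + tp == 0:
            raise ValueError("zero totals")
        counts[name] = (cn, tn, cp, tp)
    return Table1Accounting.from_counts(counts)


def run_condition_experiment(images: list[SyntheticImage],
                             translator: TranslatorPair | None,
                             classifier: PatchClassifier,
                             threshold: DecisionThreshold,
                             window_cfg: WindowConfig,
                             voting_cfg: VotingConfig,
                             model_name: str = "cnn",
                             ) -> tuple[list[DiagnosisRecord], Table1Accounting]:
    """Map, vote and diagnose every image under one pipeline condition.

    ``translator=None`` is the classification-only baseline; supplying a
    translator routes every window through the unfixed -> FFPE generator
    before classification.
    """
    records = []
    for image in images:
        label_map = compute_label_map(image, translator, classifier,
                                      threshold, window_cfg)
        voted = majority_vote(label_map, voting_cfg)
        records.append(DiagnosisRecord(
            image_id=image.image_id, true_label=image.label,
            predicted_label=diagnose_image(voted)))
    return records, score_diagnoses({model_name: records})
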