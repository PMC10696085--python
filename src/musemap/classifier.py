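"""Patch-level metastasis classifier for FFPE-domain patches.

A small convolutional network with global average pooling and a 2-node
softmax head scores each S x S x 3 patch with a metastasis probability.
Training follows the transfer-learning recipe of the diagnostic pipeline:

* patches are normalised to [0, 1] by dividing by the patch maximum;
* two phases — first only the output head is updated, then all weights —
  both with stochastic gradient descent;
* after every epoch the validation accuracy is measured and the weights
  with the best validation accuracy (earliest epoch on ties) are the ones
  returned;
* the operating threshold is the value that maximises F1 on the
  validation scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from . import nn
from .synthetic import PatchDataset


def normalize_clf(patch: np.ndarray) -> np.ndarray:
    """Scale a patch to [0, 1] by its own maximum (all-zero stays all-zero)."""
    patch = np.asarray(patch, dtype=np.float32)
    if patch.min() < 0:
        raise ValueError("input values must be non-negative")
    top = patch.max()
    return patch / top if top > 0 else patch.copy()


@dataclass(frozen=True)
class DecisionThreshold:
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"threshold must be in [0,1], got {self.value}")


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    f1: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class ClfTrainConfig:
    phase1_epochs: int = 3
    phase2_epochs: int = 16
    learning_rate: float = 0.05
    batch_size: int = 16
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.phase1_epochs < 0 or self.phase2_epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _f1_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> DecisionThreshold:
    """F1-maximising threshold over candidate cut points.

    Candidates are the midpoints between consecutive sorted unique scores
    plus the endpoints {0, 1}; prediction is positive iff score >= t; ties
    in F1 resolve to the smallest threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("need both classes to select a threshold")
    uniq = np.unique(scores)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    candidates = np.unique(candidates)
    best_t, best_f1 = 0.0, -1.0
    for t in candidates:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = _f1_from_counts(tp, fp, fn)
        if f1 > best_f1 + 1e-12:
            best_t, best_f1 = float(t), f1
    return DecisionThreshold(best_t)


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    t: DecisionThreshold) -> EvalMetrics:
    """Accuracy, F1 and rank-based AUC (ties count half) at threshold t."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have matching lengths")
    if scores.size == 0:
        raise ValueError("empty input")
    pred = scores >= t.value
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    acc = (tp + tn) / scores.size
    f1 = _f1_from_counts(tp, fp, fn)
    auc = float(roc_auc_score(labels, scores)) if labels.min() != labels.max() else float("nan")
    return EvalMetrics(acc, f1, auc, tp, fp, tn, fn)


def build_classifier_net(channels: tuple[int, ...] = (8, 16, 32),
                         rng: np.random.Generator | None = None) -> nn.Sequential:
    """Strided conv stack -> global average pooling -> 2-node head."""
    rng = rng or np.random.default_rng(0)
    layers: list[nn.Layer] = []
    c_in = 3
    for c_out in channels:
        layers += [nn.Conv2d(c_in, c_out, 3, stride=2, rng=rng), nn.ReLU()]
        c_in = c_out
    layers += [nn.GlobalAvgPool(), nn.Dense(c_in, 2, rng=rng)]
    return nn.Sequential(*layers)


class PatchClassifier(BaseEstimator, ClassifierMixin):
    """CNN patch scorer with two-phase SGD training and best-val checkpointing.

    ``fit(X, y, X_val=..., y_val=...)`` takes (N, S, S, 3) patches in
    [0, 255] and integer labels (1 = metastasis-positive).  When a
    validation split is given, the returned weights are the epoch with the
    highest validation accuracy and ``threshold_`` is the F1-maximising
    operating point on the validation scores; otherwise the training data
    double as validation.
    """

    def __init__(self, phase1_epochs: int = 3, phase2_epochs: int = 16,
                 learning_rate: float = 0.05, batch_size: int = 16,
                 channels: tuple[int, ...] = (8, 16, 32), momentum: float = 0.9,
                 random_state: int = 0):
        self.phase1_epochs = phase1_epochs
        self.phase2_epochs = phase2_epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.channels = channels
        self.momentum = momentum
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> "PatchClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y).astype(int)
        if np.unique(y).size < 2:
            raise ValueError("training set must contain both classes")
        if X_val is None:
            X_val, y_val = X, y
        X_val = np.asarray(X_val, dtype=np.float32)
        y_val = np.asarray(y_val).astype(int)
        if np.unique(y_val).size < 2:
            raise ValueError("validation set must contain both classes")

        rng = np.random.default_rng(self.random_state)
        self.net_ = build_classifier_net(tuple(self.channels), rng)
        head = self.net_.layers()[-1]  # the 2-node Dense output
        xn = self._prep(X)
        xv = self._prep(X_val)

        history: list[dict[str, float]] = []
        best = (-1.0, None, -1)  # (val_acc, weights, epoch index)
        epoch_idx = 0
        for phase, epochs, nets in (
                (1, self.phase1_epochs, [head]),
                (2, self.phase2_epochs, [self.net_])):
            if epochs == 0:
                continue
            opt = nn.SGD(nets, self.learning_rate, self.momentum)
            for _ in range(epochs):
                order = rng.permutation(len(xn))
                losses = []
                for i in range(0, len(xn), self.batch_size):
                    idx = order[i:i + self.batch_size]
                    nn.zero_grads(self.net_)
                    z, cache = self.net_.forward(xn[idx])
                    loss, dz = nn.cross_entropy_with_logits(z, y[idx])
                    self.net_.backward(cache, dz)
                    opt.step()
                    losses.append(loss)
                val_acc = self._accuracy(xv, y_val)
                history.append({"epoch": float(epoch_idx), "phase": float(phase),
                                "train_loss": float(np.mean(losses)),
                                "val_accuracy": val_acc})
                if val_acc > best[0]:  # strict: ties keep the earliest epoch
                    best = (val_acc, nn.get_weights(self.net_), epoch_idx)
                epoch_idx += 1

        if best[1] is not None:
            nn.set_weights(self.net_, best[1])
        self.history_ = history
        self.best_epoch_ = best[2]
        self.best_val_accuracy_ = best[0]
        self.classes_ = np.array([0, 1])
        val_scores = self._scores(xv)
        if np.unique(y_val).size == 2:
            self.threshold_ = select_threshold(val_scores, y_val)
        else:  # pragma: no cover - guarded above
            self.threshold_ = DecisionThreshold(0.5)
        return self

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _prep(X: np.ndarray) -> np.ndarray:
        out = np.stack([normalize_clf(p) for p in X])
        return np.ascontiguousarray(np.transpose(out, (0, 3, 1, 2)), dtype=np.float32)

    def _scores(self, xn: np.ndarray, chunk: int = 256) -> np.ndarray:
        outs = []
        for i in range(0, len(xn), chunk):
            z, _ = self.net_.forward(xn[i:i + chunk])
            outs.append(nn.softmax(z)[:, 1])
        return np.concatenate(outs)

    def _accuracy(self, xn: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean((self._scores(xn) >= 0.5) == (y == 1)))

    # -- inference --------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = self._scores(self._prep(np.asarray(X, dtype=np.float32)))
        return np.column_stack([1 - s, s])

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class softmax probabilities, one per patch."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        t = getattr(self, "threshold_", DecisionThreshold(0.5))
        return (self.decision_scores(X) >= t.value).astype(int)

    def save(self, path) -> None:
        """Checkpoint weights, architecture and operating threshold (.npz)."""
        payload = {}
        for i, layer in enumerate(self.net_.layers()):
            for k, v in layer.params.items():
                payload[f"clf/{i}/{k}"] = v
        payload["channels"] = np.array(self.channels)
        t = getattr(self, "threshold_", DecisionThreshold(0.5))
        payload["threshold"] = np.array(t.value)
        np.savez(path, **payload)

    @classmethod
    def from_file(cls, path) -> "PatchClassifier":
        with np.load(path) as archive:
            channels = tuple(int(c) for c in archive["channels"])
            clf = cls(channels=channels)
            clf.net_ = build_classifier_net(channels)
            for i, layer in enumerate(clf.net_.layers()):
                for k in layer.params:
                    layer.params[k][...] = archive[f"clf/{i}/{k}"]
            clf.threshold_ = DecisionThreshold(float(archive["threshold"]))
        clf.classes_ = np.array([0, 1])
        return clf


def train_classifier(train: PatchDataset, val: PatchDataset,
                     cfg: ClfTrainConfig = ClfTrainConfig()
                     ) -> tuple[PatchClassifier, list[dict]]:
    """Functional wrapper around :class:`PatchClassifier`."""
    x, y = train.as_arrays()
    xv, yv = val.as_arrays()
    clf = PatchClassifier(
        phase1_epochs=cfg.phase1_epochs, phase2_epochs=cfg.phase2_epochs,
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        random_state=cfg.rng_seed,
    ).fit(x, y, X_val=xv, y_val=yv)
    return clf, clf.history_
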