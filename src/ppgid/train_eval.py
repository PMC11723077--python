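"""Dataset splitting, training with early stopping, and evaluation reports.

The split is stratified per subject so every class appears in both train and
test. Training minimizes softmax cross-entropy with one of three
hyperparameter presets (batch size / hidden activation / optimizer /
learning rate), monitors validation loss carved from the training split,
halts when it fails to improve for ``patience`` consecutive epochs and
restores the best-validation weights. Evaluation produces the confusion
matrix and per-class + macro/weighted precision, recall and F1 from the
standard definitions; a class with no true or no predicted instances gets 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .nn.core import softmax_cross_entropy
from .nn.model import PpgNet
from .nn.optim import make_optimizer
from .types import LabelledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TrainSetting",
    "SETTINGS",
    "EvalReport",
    "split_dataset",
    "dataset_to_arrays",
    "train",
    "evaluate",
    "ablation",
    "TrainHistory",
]


@dataclass(frozen=True)
class TrainSetting:
    """One hyperparameter preset of the three-way ablation grid."""

    setting_id: int
    batch_size: int
    hidden_activation: str
    optimizer: str
    learning_rate: float


# The three ablation presets. Setting 1's activation entry is the model
# default (Swish hidden activations); softmax is always the output layer.
SETTINGS: dict[int, TrainSetting] = {
    1: TrainSetting(1, batch_size=16, hidden_activation="swish", optimizer="sgd", learning_rate=0.01),
    2: TrainSetting(2, batch_size=32, hidden_activation="relu", optimizer="adam", learning_rate=0.001),
    3: TrainSetting(3, batch_size=64, hidden_activation="leaky_relu", optimizer="rmsprop", learning_rate=0.0001),
}


def split_dataset(
    data: LabelledDataset,
    train_frac: float = 0.8,
    rng: Optional[np.random.Generator] = None,
) -> tuple[LabelledDataset, LabelledDataset]:
    """Stratified per-subject train/test partition.

    Per subject, ``round(train_frac * count)`` records go to train and the
    rest to test; membership is randomized by ``rng`` but deterministic for
    a fixed seed.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = rng or np.random.default_rng(0)
    by_subject: dict[str, list[int]] = {}
    for i, rec in enumerate(data):
        by_subject.setdefault(rec.subject_id, []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for sid in data.subject_ids:
        idx = np.array(by_subject[sid])
        if idx.size < 2:
            raise ValueError(f"subject {sid} has {idx.size} record(s); need >= 2 to split")
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both sides non-empty
        perm = rng.permutation(idx.size)
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return data.subset(sorted(train_idx), split="train"), data.subset(sorted(test_idx), split="test")


def dataset_to_arrays(
    data: LabelledDataset, classes: Optional[Sequence[str]] = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack raster payloads into (X, y, classes); y holds class indices."""
    classes = list(classes) if classes is not None else sorted(set(data.labels))
    index = {c: i for i, c in enumerate(classes)}
    X = np.stack([np.asarray(r.payload, dtype=float) for r in data])
    y = np.array([index[r.subject_id] for r in data], dtype=int)
    return X, y, classes


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0  # last epoch actually run (1-based)
    best_epoch: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )


def _eval_loss_acc(model: PpgNet, X: np.ndarray, y: np.ndarray, batch: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(X), batch):
        logits = model.forward_logits(X[i : i + batch], train=False)
        loss, _ = softmax_cross_entropy(logits, y[i : i + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train(
    model: PpgNet,
    train_data: LabelledDataset | tuple[np.ndarray, np.ndarray],
    setting: TrainSetting = SETTINGS[2],
    epochs: int = 25,
    patience: int = 10,
    val_frac: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    classes: Optional[Sequence[str]] = None,
    val_loss_override: Optional[Sequence[float]] = None,
) -> TrainHistory:
    """Train in place; returns the per-epoch history.

    A validation fraction is carved from the training data (after any
    augmentation) to monitor early stopping; the weights from the best
    validation epoch are restored at the end. ``val_loss_override`` replaces
    the measured validation losses (used to exercise the stopping rule
    deterministically).
    """
    rng = rng or np.random.default_rng(0)
    if isinstance(train_data, LabelledDataset):
        if len(train_data) == 0:
            raise ValueError("empty training data")
        X, y, _ = dataset_to_arrays(train_data, classes)
    else:
        X, y = train_data
        if len(X) == 0:
            raise ValueError("empty training data")

    n_val = int(round(val_frac * len(X)))
    perm = rng.permutation(len(X))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
    monitor_val = len(Xval) > 0 or val_loss_override is not None

    opt = make_optimizer(setting.optimizer, model.params, setting.learning_rate)
    hist = TrainHistory()
    best_loss = np.inf
    best_state = model.get_state()
    stale = 0
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(Xtr))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), setting.batch_size):
            idx = order[i : i + setting.batch_size]
            opt.zero_grad()
            logits = model.forward_logits(Xtr[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, ytr[idx])
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == ytr[idx]).sum())
        hist.train_loss.append(ep_loss / len(Xtr))
        hist.train_acc.append(ep_correct / len(Xtr))

        if val_loss_override is not None:
            vloss, vacc = float(val_loss_override[epoch - 1]), float("nan")
        elif monitor_val:
            vloss, vacc = _eval_loss_acc(model, Xval, yval)
        else:
            vloss, vacc = hist.train_loss[-1], hist.train_acc[-1]
        hist.val_loss.append(vloss)
        hist.val_acc.append(vacc)
        hist.stopped_epoch = epoch

        if vloss < best_loss:
            best_loss = vloss
            best_state = model.get_state()
            hist.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                logger.info("early stop at epoch %d (best epoch %d)", epoch, hist.best_epoch)
                break
    model.set_state(best_state)
    return hist


@dataclass
class EvalReport:
    """Confusion matrix plus per-class and averaged classification metrics."""

    classes: list[str]
    confusion: np.ndarray  # rows = true class, cols = predicted class
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def _weighted(self, metric: np.ndarray) -> float:
        return float((metric * self.support).sum() / self.support.sum())

    @property
    def weighted_precision(self) -> float:
        return self._weighted(self.precision)

    @property
    def weighted_recall(self) -> float:
        return self._weighted(self.recall)

    @property
    def weighted_f1(self) -> float:
        return self._weighted(self.f1)

    def to_dataframe(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "class": self.classes,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            }
        )
        footer = pd.DataFrame(
            {
                "class": ["macro avg", "weighted avg"],
                "precision": [self.macro_precision, self.weighted_precision],
                "recall": [self.macro_recall, self.weighted_recall],
                "f1": [self.macro_f1, self.weighted_f1],
                "support": [self.support.sum()] * 2,
            }
        )
        return pd.concat([rows, footer], ignore_index=True)


def report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence[str]
) -> EvalReport:
    n = len(classes)
    confusion = np.zeros((n, n), dtype=int)
    np.add.at(confusion, (y_true, y_pred), 1)
    tp = np.diag(confusion).astype(float)
    pred_count = confusion.sum(axis=0).astype(float)
    support = confusion.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_count > 0, tp / np.maximum(pred_count, 1), 0.0)
        recall = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    if (pred_count == 0).any() or (support == 0).any():
        logger.warning("classes with zero predictions or zero support scored as 0")
    accuracy = float(tp.sum() / confusion.sum())
    return EvalReport(
        classes=list(classes),
        confusion=confusion,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        accuracy=accuracy,
    )


def evaluate(
    model: PpgNet,
    test_data: LabelledDataset | tuple[np.ndarray, np.ndarray],
    classes: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Argmax predictions on the test split -> confusion matrix + metrics."""
    if isinstance(test_data, LabelledDataset):
        if len(test_data) == 0:
            raise ValueError("empty test data")
        X, y, classes = dataset_to_arrays(test_data, classes)
    else:
        X, y = test_data
        if len(X) == 0:
            raise ValueError("empty test data")
        if classes is None:
            classes = [str(c) for c in range(int(y.max()) + 1)]
    preds = []
    for i in range(0, len(X), 64):
        preds.append(model.predict(X[i : i + 64]))
    return report_from_predictions(y, np.concatenate(preds), classes)


def ablation(
    settings: Sequence[TrainSetting],
    data_variants: dict[str, tuple[LabelledDataset, LabelledDataset]],
    model_factory,
    epochs: int = 25,
    patience: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/evaluate every (setting x variant) cell; returns a tidy table.

    ``model_factory(setting, n_classes, seed)`` must return a fresh model.
    """
    rows = []
    for variant, (train_ds, test_ds) in data_variants.items():
        classes = sorted(set(train_ds.labels) | set(test_ds.labels))
        for setting in settings:
            model = model_factory(setting, len(classes), seed)
            train(
                model,
                train_ds,
                setting=setting,
                epochs=epochs,
                patience=patience,
                rng=np.random.default_rng(seed),
                classes=classes,
            )
            report = evaluate(model, test_ds, classes=classes)
            rows.append(
                {
                    "setting_id": setting.setting_id,
                    "variant": variant,
                    "accuracy": report.accuracy,
                    "macro_f1": report.macro_f1,
                    "weighted_f1": report.weighted_f1,
                }
            )
    return pd.DataFrame(rows)
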