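"""Training harness: split, mini-batch Adam training with early stopping and
learning-rate reduction on plateau, and support-weighted classification
metrics.

Protocol defaults: Adam at learning rate 1e-3, sparse categorical
cross-entropy on integer labels, batch size 16, at most 50 epochs, early
stopping after 10 epochs without validation-loss improvement (best weights
restored), learning rate reduced by a factor of 0.1 after a 3-epoch
plateau, and 20% of the training split held out for validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from . import engine
from .data import LabeledImageSet
from .graph import ModelGraph

__all__ = ["TrainConfig", "MetricsReport", "split_train_test", "train",
           "compute_metrics", "predict_labels"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 50
    early_stop_patience: int = 10
    lr_reduce_factor: float = 0.1
    lr_reduce_patience: int = 3
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.early_stop_patience < 1 or self.lr_reduce_patience < 1:
            raise ValueError("patience values must be >= 1")


@dataclass
class MetricsReport:
    """Support-weighted accuracy/precision/recall/F1 (percent, 2 decimals)
    and the integer confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: list
    epochs_run: int = 0
    stopped_epoch: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def split_train_test(dataset: LabeledImageSet, train_fraction: float = 0.8, seed: int = 0):
    """Seeded uniform random split (no per-class stratification)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(n * train_fraction))
    return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])


def _rescale(features: np.ndarray) -> np.ndarray:
    return np.asarray(features, dtype=float) / 255.0


class PlateauSchedule:
    """Early stopping + reduce-on-plateau bookkeeping.

    Tracks the best validation loss; after ``lr_reduce_patience`` epochs
    without improvement the learning rate is multiplied by
    ``lr_reduce_factor``, and after ``early_stop_patience`` epochs training
    stops (the caller restores the best weights).
    """

    def __init__(self, config: "TrainConfig"):
        self.config = config
        self.lr = config.learning_rate
        self.best_loss = np.inf
        self.since_best = 0
        self.since_reduce = 0

    def update(self, val_loss: float) -> tuple:
        """Returns (improved, stop) and adjusts ``self.lr`` on plateau."""
        improved = val_loss < self.best_loss - 1e-12
        if improved:
            self.best_loss = val_loss
            self.since_best = 0
            self.since_reduce = 0
        else:
            self.since_best += 1
            self.since_reduce += 1
            if self.since_reduce >= self.config.lr_reduce_patience:
                self.lr *= self.config.lr_reduce_factor
                self.since_reduce = 0
        return improved, self.since_best >= self.config.early_stop_patience


def _evaluate_loss(graph, weights, x, y, batch_size=64):
    losses = []
    for s in range(0, len(x), batch_size):
        acts, _ = engine.forward(graph, weights, x[s : s + batch_size], keep=set())
        p = acts[graph.output_id]
        yb = y[s : s + batch_size]
        losses.append(-np.log(p[np.arange(len(yb)), yb] + 1e-12))
    all_l = np.concatenate(losses)
    return float(all_l.mean())


def train(graph: ModelGraph, weights: dict, train_set: LabeledImageSet, config: TrainConfig):
    """Mini-batch training; returns (trained weights, history).

    A validation split of ``validation_fraction`` is carved from
    ``train_set`` with the config seed.  History records per-epoch train
    loss/accuracy, validation loss, and learning rate.
    """
    rng = np.random.default_rng(config.seed)
    n = len(train_set)
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * config.validation_fraction)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    x_tr = _rescale(train_set.features[tr_idx])
    y_tr = train_set.labels[tr_idx]
    x_val = _rescale(train_set.features[val_idx])
    y_val = train_set.labels[val_idx]

    state = engine.AdamState(weights)
    schedule = PlateauSchedule(config)
    history = {"epoch": [], "train_loss": [], "train_acc": [], "val_loss": [], "lr": []}
    best_weights = engine.copy_weights(weights)
    stopped_epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x_tr))
        losses, correct = [], 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            loss, probs, grads = engine.forward_backward(graph, weights, x_tr[idx], y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}; "
                    "reduce the learning rate or check the input scale"
                )
            engine.adam_step(weights, grads, state, schedule.lr)
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == y_tr[idx]).sum())
        val_loss = _evaluate_loss(graph, weights, x_val, y_val)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.sum(losses) / len(x_tr)))
        history["train_acc"].append(correct / len(x_tr))
        history["val_loss"].append(val_loss)
        history["lr"].append(schedule.lr)
        improved, stop = schedule.update(val_loss)
        if improved:
            best_weights = engine.copy_weights(weights)
        if stop:
            stopped_epoch = epoch
            break
    history["stopped_epoch"] = stopped_epoch
    return best_weights, history


def predict_labels(graph: ModelGraph, weights: dict, features: np.ndarray,
                   batch_size: int = 64) -> np.ndarray:
    """Argmax class predictions on 0–255-domain images."""
    x = _rescale(features)
    preds = []
    for s in range(0, len(x), batch_size):
        acts, _ = engine.forward(graph, weights, x[s : s + batch_size], keep=set())
        preds.append(acts[graph.output_id].argmax(axis=1))
    return np.concatenate(preds)


def compute_metrics(true_labels, predicted_labels, n_classes: int,
                    epochs_run: int = 0, stopped_epoch: int = 0) -> MetricsReport:
    """Confusion matrix plus support-weighted precision/recall/F1.

    Weighted recall equals plain accuracy by construction, which is why the
    weighted average is the appropriate reading of reports in which the two
    nearly coincide.
    """
    y_true = np.asarray(true_labels, dtype=int)
    y_pred = np.asarray(predicted_labels, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("label vectors must be non-empty and of equal length")
    labels = np.arange(n_classes)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0
    )
    acc = float((y_true == y_pred).mean())
    return MetricsReport(
        accuracy=round(acc * 100, 2),
        precision=round(float(prec) * 100, 2),
        recall=round(float(rec) * 100, 2),
        f1=round(float(f1) * 100, 2),
        confusion=cm.astype(int).tolist(),
        epochs_run=epochs_run,
        stopped_epoch=stopped_epoch,
    )
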