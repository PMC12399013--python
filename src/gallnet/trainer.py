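"""Training protocol: Adam with time-based learning-rate decay, sparse
categorical cross-entropy plus an L2 penalty on dense weights, on-the-fly
augmentation of the training stream, early stopping on validation
accuracy (patience 3) and checkpointing on minimum validation loss.

Reported losses (training and validation) include the L2 penalty, i.e.
they are the optimized objective; the checkpoint criterion monitors that
same validation loss.  A whole run is reproducible from ``TrainConfig.seed``:
the epoch shuffles, augmentation draws and dropout masks come from three
independent child streams of that seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import CLASS_NAMES, nn
from .data_io import AugmentationConfig, DatasetSplit, ImageRecord, augment
from .model_core import Model
from .nn import softmax

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "sparse_categorical_crossentropy",
    "learning_rate_at",
    "early_stop_epoch",
    "evaluate",
    "train",
]

PROBABILITY_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    decay: float = 0.2
    decay_schedule: str = "time"   # "time", "exponential" or "none"
    batch_size: int = 32
    max_epochs: int = 10
    patience: int = 3
    l2: float = 0.01
    dropout: float = 0.1
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-7
    augment: bool = True
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max epochs")
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.decay < 0:
            raise ValueError("decay must be nonnegative")


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    checkpoint_epoch: int | None = None
    stop_reason: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epoch,
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "learning_rate": self.learning_rate,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sparse_categorical_crossentropy(probabilities: np.ndarray,
                                    labels: np.ndarray | int) -> float:
    """Mean of -log p(true class), with a 1e-12 probability floor."""
    probs = np.atleast_2d(np.asarray(probabilities, dtype=float))
    labels = np.atleast_1d(np.asarray(labels))
    if labels.ndim != 1 or len(labels) != len(probs):
        raise ValueError("labels must be one index per probability vector")
    n_classes = probs.shape[1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise IndexError(f"class index out of range 0..{n_classes - 1}")
    picked = probs[np.arange(len(probs)), labels]
    return float(-np.log(np.maximum(picked, PROBABILITY_FLOOR)).mean())


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Per-epoch schedule; the default is the classic time-based decay
    base / (1 + decay * epoch), so epoch 0 runs at the base rate."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    base, d = config.learning_rate, config.decay
    if config.decay_schedule == "none" or d == 0:
        return base
    if config.decay_schedule == "time":
        return base / (1.0 + d * epoch)
    if config.decay_schedule == "exponential":
        return base * float(np.exp(-d * epoch))
    raise ValueError(f"unknown decay schedule {config.decay_schedule!r}")


def early_stop_epoch(val_accuracies, patience: int) -> int | None:
    """Index of the epoch after which training stops — the first epoch
    with no strict improvement of the best-so-far during the last
    ``patience`` epochs — or None if never triggered."""
    if patience < 1:
        raise ValueError("patience must be >= 1")
    best = -np.inf
    stale = 0
    for e, acc in enumerate(val_accuracies):
        if acc > best:
            best = acc
            stale = 0
        else:
            stale += 1
        if stale >= patience:
            return e
    return None


def _l2_penalty(model: Model) -> float:
    return sum(layer.l2_penalty() for layer in model.layers
               if isinstance(layer, nn.Dense))


def _labels_for(records: list[ImageRecord], class_names) -> np.ndarray:
    index = {name: i for i, name in enumerate(class_names)}
    try:
        return np.array([index[r.label] for r in records])
    except KeyError as exc:
        raise ValueError(f"record label {exc} not in class set")


def evaluate(model: Model, records: list[ImageRecord],
             class_names=CLASS_NAMES, batch_size: int = 64):
    """Inference-mode loss (cross-entropy + L2 penalty) and accuracy."""
    if not records:
        raise ValueError("cannot evaluate on an empty record list")
    labels = _labels_for(records, class_names)
    x = np.stack([r.pixels for r in records])[..., None]
    probs = model.predict_proba(x, batch_size=batch_size)
    loss = sparse_categorical_crossentropy(probs, labels) + _l2_penalty(model)
    acc = float((probs.argmax(axis=1) == labels).mean())
    return loss, acc


def train(model: Model, split: DatasetSplit, config: TrainConfig,
          class_names=CLASS_NAMES, verbose: bool = False):
    """Run the full training protocol; returns ``(model, history)`` with
    the model restored to its checkpointed (minimum validation loss)
    state."""
    if not split.train:
        raise ValueError("training set is empty")
    if not split.validation:
        raise ValueError("validation set is empty (early stopping undefined)")

    shuffle_rng, augment_rng, dropout_rng = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(3))
    model.set_dropout_rng(dropout_rng)

    labels = _labels_for(split.train, class_names)
    n = len(split.train)
    optimizer = nn.Adam(model.param_grad_pairs(), lr=config.learning_rate,
                        beta1=config.beta1, beta2=config.beta2,
                        eps=config.adam_eps)
    history = TrainingHistory()
    best_val_loss = np.inf
    best_weights = None
    history.stop_reason = "max_epochs"

    for epoch in range(config.max_epochs):
        lr = learning_rate_at(epoch, config)
        optimizer.lr = lr
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if config.augment:
                xb = np.stack([augment(split.train[i].pixels,
                                       config.augmentation, augment_rng)
                               for i in idx])
            else:
                xb = np.stack([split.train[i].pixels for i in idx])
            yb = labels[idx]
            logits = model.forward(xb[..., None], training=True)
            probs = softmax(logits)
            batch_loss = sparse_categorical_crossentropy(probs, yb) \
                + _l2_penalty(model)
            dlogits = (probs - np.eye(logits.shape[1])[yb]) / len(idx)
            model.backward(dlogits.astype(model.dtype))
            optimizer.step()
            epoch_loss += batch_loss * len(idx)
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
        # refresh inference-mode BN statistics under the current weights
        # (a class-balanced strided subsample of the unaugmented training
        # stream) so validation metrics reflect the model being trained
        step = max(1, int(np.ceil(n / 256)))
        calib_idx = np.arange(0, n, step)
        calib = np.stack([split.train[i].pixels for i in calib_idx])[..., None]
        model.reestimate_bn_statistics(calib, batch_size=config.batch_size)
        val_loss, val_acc = evaluate(model, split.validation, class_names)

        history.epoch.append(epoch)
        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(epoch_correct / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(lr)
        if verbose:
            print(f"epoch {epoch}: loss {epoch_loss / n:.4f} "
                  f"acc {epoch_correct / n:.4f} val_loss {val_loss:.4f} "
                  f"val_acc {val_acc:.4f} lr {lr:.2e}")

        if val_loss < best_val_loss:  # strict: earliest minimal epoch kept
            best_val_loss = val_loss
            best_weights = model.get_weights()
            history.checkpoint_epoch = epoch
        if early_stop_epoch(history.val_accuracy, config.patience) == epoch:
            history.stop_reason = "early_stopping"
            break

    if best_weights is not None:
        model.set_weights(best_weights)
    return model, history
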