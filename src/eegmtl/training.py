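"""Joint multi-task training.

The loss is the (weighted) sum of per-task mean cross-entropies; the
optimizer is Adam with L2 weight decay under a step-decay learning-rate
schedule ``lr_t = lr * gamma ** floor(t / step_size)`` (epoch index t from
0).  Early stopping monitors a validation quantity with best-weights
restoration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, LabelError, ParameterError
from .network import MultiTaskNet, ForwardOutput
from .nn import Adam
from .nn.attention import softmax
from .segmentation import LabelVocab, segments_to_arrays

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "LossBreakdown",
    "joint_loss",
    "lr_at_epoch",
    "train",
    "set_global_seed",
]

_GLOBAL_SEED = 0


def set_global_seed(seed: int) -> None:
    """Set the process-wide default seed.

    Components that are not handed an explicit seed derive theirs from this
    value.  Determinism is best-effort on a single device: two runs with the
    same seed on the same machine produce identical histories.
    """
    global _GLOBAL_SEED
    _GLOBAL_SEED = int(seed)
    np.random.seed(seed % (2**32))


def get_global_seed() -> int:
    return _GLOBAL_SEED


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference setup)."""

    lr: float = 1e-4
    weight_decay: float = 1e-4
    gamma: float = 0.5
    step_size: int = 5
    epochs: int = 20
    batch_size: int = 16
    patience: int = 5
    monitor: str = "mean_accuracy"  # or "total_loss"
    loss_weights: tuple = (1.0, 1.0, 1.0)
    seed: int = 0
    normalize_windows: bool = True

    def __post_init__(self):
        self.loss_weights = tuple(float(w) for w in self.loss_weights)
        if self.lr <= 0:
            raise ConfigError(f"lr must be > 0, got {self.lr}")
        if not 0 < self.gamma <= 1:
            raise ConfigError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.step_size < 1 or self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("step_size, batch_size and epochs must be >= 1")
        if self.patience < 0:
            raise ConfigError(f"patience must be >= 0, got {self.patience}")
        if self.monitor not in ("mean_accuracy", "total_loss"):
            raise ConfigError(f"monitor must be 'mean_accuracy' or 'total_loss', got {self.monitor!r}")
        if any(w < 0 for w in self.loss_weights) or not any(self.loss_weights):
            raise ConfigError("loss_weights must be non-negative and not all zero")

    def weight(self, task: str) -> float:
        return dict(zip(("bio", "lang", "dev"), self.loss_weights))[task]


@dataclass
class LossBreakdown:
    """Total loss and its per-task cross-entropy components."""

    total: float
    bio: float = float("nan")
    lang: float = float("nan")
    dev: float = float("nan")


def lr_at_epoch(t: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: ``lr * gamma ** floor(t / step_size)``, t from 0."""
    if t < 0:
        raise ParameterError(f"epoch index must be >= 0, got {t}")
    return cfg.lr * cfg.gamma ** (t // cfg.step_size)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n, k = logits.shape
    y = np.asarray(y)
    bad = (y < 0) | (y >= k)
    if bad.any():
        i = int(np.argmax(bad))
        raise LabelError(f"label {y[i]} at index {i} outside [0, {k})")
    p = softmax(logits.astype(np.float64), axis=-1)
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-300))))
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def joint_loss(
    out: ForwardOutput,
    labels: Mapping,
    weights: Sequence[float] = (1.0, 1.0, 1.0),
) -> LossBreakdown:
    """Weighted sum of per-task mean cross-entropies for the exposed tasks."""
    w = dict(zip(("bio", "lang", "dev"), weights))
    parts = {}
    total = 0.0
    for task in out.tasks:
        loss, _ = cross_entropy(out.logits(task), labels[task])
        parts[task] = loss
        total += w[task] * loss
    return LossBreakdown(total=total, **parts)


@dataclass
class TrainHistory:
    """Per-epoch log of losses, validation metrics and learning rate."""

    epochs: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False
    seed: int = 0

    def append(self, **row) -> None:
        self.epochs.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)


def _as_arrays(data, vocab: LabelVocab | None, normalize: bool):
    if isinstance(data, tuple):
        return data
    if vocab is None:
        vocab = LabelVocab.from_segments(data)
    return segments_to_arrays(data, vocab, normalize=normalize)


def _evaluate_arrays(model: MultiTaskNet, X, y, weights, batch_size: int = 64):
    """Validation loss and accuracy per exposed task (evaluation mode)."""
    model.eval()
    n = X.shape[0]
    losses = {t: 0.0 for t in model.variant.tasks}
    correct = {t: 0 for t in model.variant.tasks}
    for i in range(0, n, batch_size):
        out = model.forward(X[i : i + batch_size])
        for t in model.variant.tasks:
            loss, _ = cross_entropy(out.logits(t), y[t][i : i + batch_size])
            losses[t] += loss * out.logits(t).shape[0]
            pred = np.argmax(out.logits(t), axis=-1)
            correct[t] += int((pred == y[t][i : i + batch_size]).sum())
    losses = {t: v / n for t, v in losses.items()}
    accs = {t: c / n for t, c in correct.items()}
    w = dict(zip(("bio", "lang", "dev"), weights))
    total = sum(w[t] * losses[t] for t in losses)
    return total, losses, accs


def train(
    model: MultiTaskNet,
    train_data,
    val_data,
    cfg: TrainConfig = TrainConfig(),
    vocab: LabelVocab | None = None,
    verbose: bool = False,
):
    """Optimize ``model`` on training segments with validation-based early stopping.

    ``train_data`` / ``val_data`` are lists of :class:`Segment` or
    pre-built ``(X, y)`` pairs.  Returns ``(model, TrainHistory)``; the
    returned model carries the parameters of the best validation epoch.
    """
    Xtr, ytr = _as_arrays(train_data, vocab, cfg.normalize_windows)
    Xva, yva = _as_arrays(val_data, vocab, cfg.normalize_windows)
    if Xtr.shape[0] == 0 or Xva.shape[0] == 0:
        raise ParameterError("train and validation splits must both be non-empty")

    rng = np.random.default_rng([cfg.seed, 424243])
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = TrainHistory(seed=cfg.seed)
    best_monitor = -np.inf
    best_state = None
    best_bn = None
    bad_epochs = 0
    n = Xtr.shape[0]
    tasks = model.variant.tasks

    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(epoch, cfg)
        opt.lr = lr
        model.train()
        perm = rng.permutation(n)
        epoch_loss = {t: 0.0 for t in tasks}
        for i in range(0, n, cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            out = model.forward(Xtr[idx])
            model.zero_grad()
            grads = {}
            for t in tasks:
                loss, dlogits = cross_entropy(out.logits(t), ytr[t][idx])
                epoch_loss[t] += loss * len(idx)
                grads[t] = cfg.weight(t) * dlogits
            model.backward(grads)
            opt.step()
        epoch_loss = {t: v / n for t, v in epoch_loss.items()}
        train_total = sum(cfg.weight(t) * epoch_loss[t] for t in tasks)

        val_total, val_losses, val_accs = _evaluate_arrays(
            model, Xva, yva, cfg.loss_weights
        )
        monitor = (
            float(np.mean(list(val_accs.values())))
            if cfg.monitor == "mean_accuracy"
            else -val_total
        )
        row = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": train_total,
            **{f"train_loss_{t}": epoch_loss[t] for t in tasks},
            "val_loss": val_total,
            **{f"val_acc_{t}": val_accs[t] for t in tasks},
            "monitor": monitor,
        }
        history.append(**row)
        if verbose:
            accs = " ".join(f"{t}={val_accs[t]:.3f}" for t in tasks)
            print(f"epoch {epoch:3d} lr={lr:.2e} loss={train_total:.4f} val[{accs}]")

        if monitor > best_monitor:
            best_monitor = monitor
            history.best_epoch = epoch
            best_state = model.state_dict()
            best_bn = _batchnorm_state(model)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                history.stopped_early = True
                break

    if best_state is not None:
        model.load_state_dict(best_state)
        _restore_batchnorm(model, best_bn)
    model.eval()
    return model, history


def _batchnorm_state(model):
    from .nn import BatchNorm1d

    return [
        (m.running_mean.copy(), m.running_var.copy())
        for m in model.modules()
        if isinstance(m, BatchNorm1d)
    ]


def _restore_batchnorm(model, state):
    from .nn import BatchNorm1d

    mods = [m for m in model.modules() if isinstance(m, BatchNorm1d)]
    for m, (mean, var) in zip(mods, state):
        m.running_mean = mean.copy()
        m.running_var = var.copy()
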