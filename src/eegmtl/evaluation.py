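"""Evaluation reports and the comparative / ablation benchmark harness.

Accuracy is reported per sliding window (segment level); an optional
trial-level accuracy aggregates window predictions by majority vote, since
a deployed system decides once per trial.  Confusion matrices follow the
convention rows = true class, columns = predicted class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .errors import ParameterError
from .network import ModelConfig, MultiTaskNet, build_model
from .segmentation import LabelVocab, Segment, segments_to_arrays
from .training import TrainConfig, train

__all__ = ["EvalReport", "BenchmarkTable", "evaluate", "run_benchmark"]

_CLASS_COUNTS = {"bio": None, "lang": 2, "dev": 2}


@dataclass
class EvalReport:
    """Per-task accuracies and confusion matrices on one split."""

    accuracy: dict                  # task -> fraction in [0, 1]
    confusion: dict                 # task -> (K, K) integer array
    n_segments: int
    split: str = "test"
    seed: int = 0
    variant: str = "full"
    trial_accuracy: dict = field(default_factory=dict)  # majority vote per trial

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.accuracy.values())))

    def to_dict(self) -> dict:
        return {
            "accuracy": {k: float(v) for k, v in self.accuracy.items()},
            "trial_accuracy": {k: float(v) for k, v in self.trial_accuracy.items()},
            "confusion": {k: v.tolist() for k, v in self.confusion.items()},
            "n_segments": self.n_segments,
            "split": self.split,
            "seed": self.seed,
            "variant": self.variant,
        }


def _predict(model: MultiTaskNet, X: np.ndarray, batch_size: int = 64) -> dict:
    model.eval()
    preds = {t: [] for t in model.variant.tasks}
    for i in range(0, X.shape[0], batch_size):
        out = model.forward(X[i : i + batch_size])
        for t in model.variant.tasks:
            # ties broken toward the lowest class index (np.argmax convention)
            preds[t].append(np.argmax(out.logits(t), axis=-1))
    return {t: np.concatenate(v) for t, v in preds.items()}


def evaluate(
    model: MultiTaskNet,
    segments: Sequence[Segment],
    vocab: LabelVocab | None = None,
    split: str = "test",
    seed: int = 0,
    normalize: bool = True,
) -> EvalReport:
    """Segment-level accuracies and confusion matrices for one split."""
    if not segments:
        raise ParameterError("evaluate requires a non-empty segment list")
    if vocab is None:
        vocab = LabelVocab.from_segments(segments)
    X, y = segments_to_arrays(segments, vocab, normalize=normalize)
    preds = _predict(model, X)
    accuracy, confusion, trial_acc = {}, {}, {}
    trial_ids = np.array([s.trial_id for s in segments])
    for t, pred in preds.items():
        k = vocab.n_subjects if t == "bio" else _CLASS_COUNTS[t]
        cm = confusion_matrix(y[t], pred, labels=np.arange(k))
        confusion[t] = cm
        accuracy[t] = float(np.trace(cm) / cm.sum())
        trial_acc[t] = _majority_vote_accuracy(trial_ids, y[t], pred)
    return EvalReport(
        accuracy=accuracy,
        confusion=confusion,
        n_segments=len(segments),
        split=split,
        seed=seed,
        variant=model.variant.variant,
        trial_accuracy=trial_acc,
    )


def _majority_vote_accuracy(trial_ids, y_true, y_pred) -> float:
    correct = 0
    trials = pd.unique(trial_ids)
    for tid in trials:
        mask = trial_ids == tid
        votes = np.bincount(y_pred[mask])
        if np.argmax(votes) == y_true[mask][0]:
            correct += 1
    return float(correct / len(trials))


@dataclass
class BenchmarkTable:
    """Mean +/- sd accuracies per variant over seeds.

    The ``stt`` row aggregates three independently trained single-task
    models (one per task); every other row is one jointly trained model.
    """

    rows: list                      # dicts: variant, per-task mean/sd, average
    seeds: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def mean_average(self, variant: str) -> float:
        for row in self.rows:
            if row["variant"] == variant:
                return row["average_accuracy_mean"]
        raise KeyError(variant)


def _train_and_eval(
    variant: str,
    splits: dict,
    vocab: LabelVocab,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    seed: int,
) -> dict:
    """Train one variant on prepared splits; return task -> test accuracy."""
    cfg = TrainConfig(**{**tcfg.__dict__, "seed": seed})
    model = build_model(mcfg, variant, seed=seed)
    model, _ = train(model, splits["train"], splits["val"], cfg, vocab=vocab)
    report = evaluate(
        model, splits["test"], vocab, seed=seed, normalize=cfg.normalize_windows
    )
    return report.accuracy


def run_benchmark(
    variants: Sequence[str],
    splits: dict,
    seeds: Sequence[int],
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    vocab: LabelVocab | None = None,
) -> BenchmarkTable:
    """Train and test each variant under identical splits, per seed.

    ``splits`` maps ``train`` / ``val`` / ``test`` to segment lists shared
    by every variant.  ``variants`` may contain the meta-variant ``"stt"``,
    expanded into three single-task trainings whose accuracies fill one row.
    """
    if not seeds:
        raise ParameterError("at least one seed is required")
    if vocab is None:
        vocab = LabelVocab.from_segments(
            [*splits["train"], *splits["val"], *splits["test"]]
        )
    per_variant: dict = {v: [] for v in variants}
    for seed in seeds:
        for v in variants:
            if v == "stt":
                accs = {}
                for task in ("bio", "lang", "dev"):
                    accs.update(
                        _train_and_eval(f"stt_{task}", splits, vocab, mcfg, tcfg, seed)
                    )
            else:
                accs = _train_and_eval(v, splits, vocab, mcfg, tcfg, seed)
            accs["average"] = float(np.mean([accs["bio"], accs["lang"], accs["dev"]]))
            per_variant[v].append(accs)

    rows = []
    for v in variants:
        runs = per_variant[v]
        row = {"variant": v, "n_seeds": len(runs)}
        for key in ("bio", "lang", "dev", "average"):
            vals = np.array([r[key] for r in runs])
            prefix = "average_accuracy" if key == "average" else f"{key}_accuracy"
            row[f"{prefix}_mean"] = float(vals.mean())
            row[f"{prefix}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return BenchmarkTable(rows=rows, seeds=tuple(seeds))
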