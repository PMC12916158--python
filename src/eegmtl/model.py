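"""Public modelling objects.

The workflow mirrors statsmodels: construct a :class:`MultiTaskEEGModel`
from data, call :meth:`~MultiTaskEEGModel.fit`, and work with the returned
:class:`MultiTaskEEGResults` — trained network, training history, per-task
test accuracies, confusion matrices and a ``summary()`` table.

Example
-------
>>> from eegmtl import SynthConfig, generate_dataset, MultiTaskEEGModel
>>> recs = generate_dataset(SynthConfig(n_subjects=4, n_trials_per_cell=2,
...                                     trial_length=1000, seed=0))
>>> model = MultiTaskEEGModel.from_recordings(recs, window=500, stride=250, seed=0)
>>> res = model.fit(epochs=3)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .evaluation import EvalReport, evaluate
from .network import ModelConfig, MultiTaskNet, build_model, count_parameters
from .records import EEGRecording
from .segmentation import (
    LabelVocab,
    Segment,
    SplitAssignment,
    make_splits,
    segment_dataset,
)
from .training import TrainConfig, TrainHistory, train

__all__ = ["MultiTaskEEGModel", "MultiTaskEEGResults"]


class MultiTaskEEGModel:
    """Joint subject / language / modality classifier over EEG windows.

    Parameters
    ----------
    segments : list of Segment
        Labelled sliding windows (see :func:`eegmtl.segment_dataset`).
    splits : SplitAssignment, optional
        Train/val/test assignment; built from ``fractions`` and ``seed``
        when omitted.
    model_config, train_config : optional
        Architecture and optimization settings; ``n_subjects`` and
        ``in_channels`` are inferred from the data when not given.
    """

    def __init__(
        self,
        segments: Sequence[Segment],
        splits: SplitAssignment | None = None,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        fractions: tuple = (0.7, 0.15, 0.15),
        seed: int = 0,
    ):
        if not segments:
            raise ParameterError("no segments provided")
        self.segments = list(segments)
        self.vocab = LabelVocab.from_segments(self.segments)
        self.splits = splits if splits is not None else make_splits(self.segments, fractions, seed)
        self.seed = seed
        if model_config is None:
            model_config = ModelConfig(
                in_channels=self.segments[0].window.shape[0],
                n_subjects=self.vocab.n_subjects,
            )
        self.model_config = model_config
        self.train_config = train_config if train_config is not None else TrainConfig(seed=seed)

    @classmethod
    def from_recordings(
        cls,
        recordings: Sequence[EEGRecording],
        window: int = 1000,
        stride: int = 500,
        fractions: tuple = (0.7, 0.15, 0.15),
        seed: int = 0,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "MultiTaskEEGModel":
        """Segment aligned recordings and build the model in one step."""
        segments = segment_dataset(recordings, window, stride)
        return cls(
            segments,
            model_config=model_config,
            train_config=train_config,
            fractions=fractions,
            seed=seed,
        )

    def split_segments(self, split: str) -> list:
        return self.splits.select(self.segments, split)

    def fit(self, variant: str = "full", verbose: bool = False, **overrides) -> "MultiTaskEEGResults":
        """Train a network variant; keyword overrides patch the TrainConfig.

        Returns a results object evaluated on the held-out test split.
        """
        tcfg = replace(self.train_config, **overrides) if overrides else self.train_config
        net = build_model(self.model_config, variant, seed=tcfg.seed)
        net, history = train(
            net,
            self.split_segments("train"),
            self.split_segments("val"),
            tcfg,
            vocab=self.vocab,
            verbose=verbose,
        )
        test = self.split_segments("test")
        report = (
            evaluate(net, test, self.vocab, split="test", seed=tcfg.seed,
                     normalize=tcfg.normalize_windows)
            if test
            else None
        )
        return MultiTaskEEGResults(self, net, history, report, tcfg)


class MultiTaskEEGResults:
    """Fitted network plus history, held-out evaluation and summary table."""

    def __init__(
        self,
        model: MultiTaskEEGModel,
        network: MultiTaskNet,
        history: TrainHistory,
        report: EvalReport | None,
        train_config: TrainConfig,
    ):
        self.model = model
        self.network = network
        self.history = history
        self.report = report
        self.train_config = train_config

    @property
    def accuracy(self) -> dict:
        """Segment-level test accuracy per task."""
        return {} if self.report is None else self.report.accuracy

    @property
    def confusion(self) -> dict:
        return {} if self.report is None else self.report.confusion

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.network)

    def evaluate(self, segments: Sequence[Segment], split: str = "custom") -> EvalReport:
        """Evaluate the fitted network on an arbitrary segment list."""
        return evaluate(
            self.network,
            segments,
            self.model.vocab,
            split=split,
            seed=self.train_config.seed,
            normalize=self.train_config.normalize_windows,
        )

    def predict(self, X: np.ndarray) -> dict:
        """Class predictions per task for a ``(n, C, w)`` batch of windows."""
        out = self.network.eval().forward(X)
        return {t: np.argmax(out.logits(t), axis=-1) for t in out.tasks}

    def summary(self) -> str:
        """A compact text report in the spirit of statsmodels results."""
        lines = []
        v = self.network.variant.variant
        lines.append("Multi-task EEG classification results")
        lines.append("=" * 54)
        lines.append(f"variant: {v:<18} parameters: {self.n_parameters:,}")
        lines.append(
            f"seed: {self.train_config.seed:<6} epochs run: {self.history.n_epochs} "
            f"(best: {self.history.best_epoch}, early stop: {self.history.stopped_early})"
        )
        n_tr = len(self.model.split_segments("train"))
        n_va = len(self.model.split_segments("val"))
        n_te = len(self.model.split_segments("test"))
        lines.append(f"segments: train={n_tr} val={n_va} test={n_te}")
        if self.report is not None:
            lines.append("-" * 54)
            lines.append(f"{'task':<10}{'test accuracy':>16}{'trial accuracy':>18}")
            names = {"bio": "subject", "lang": "language", "dev": "device"}
            for t, acc in self.report.accuracy.items():
                trial = self.report.trial_accuracy.get(t, float("nan"))
                lines.append(f"{names[t]:<10}{acc:>15.1%}{trial:>17.1%}")
            if len(self.report.accuracy) > 1:
                lines.append(f"{'average':<10}{self.report.mean_accuracy:>15.1%}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def history_frame(self) -> pd.DataFrame:
        return self.history.to_frame()
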