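"""Sliding-window segmentation and leakage-safe train/val/test splits.

Trials are cut into overlapping fixed-length windows (default 1000 samples
with stride 500, i.e. 50% overlap).  Because neighbouring windows of one
trial share half their samples, splits are assigned at the *trial* level by
default: every window of a trial lands in the same partition, so no test
window is a near-duplicate of a training window.  A window-level mode exists
for comparison with evaluations that ignore this leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .records import DEVICES, LANGUAGES, EEGRecording

__all__ = [
    "Segment",
    "SplitAssignment",
    "sliding_windows",
    "segment_dataset",
    "make_splits",
    "zscore_window",
    "LabelVocab",
    "segments_to_arrays",
]


@dataclass
class Segment:
    """One fixed-length window of a trial, carrying the trial's labels."""

    window: np.ndarray          # (channels, w)
    labels: tuple               # (subject_id, language, device)
    trial_id: str
    start: int                  # sample offset within the source trial

    @property
    def subject_id(self) -> str:
        return self.labels[0]

    @property
    def language(self) -> str:
        return self.labels[1]

    @property
    def device(self) -> str:
        return self.labels[2]


def sliding_windows(rec: EEGRecording, w: int = 1000, s: int = 500) -> list:
    """Cut one trial into overlapping windows of length ``w`` at stride ``s``.

    Start offsets are ``0, s, 2s, …`` up to the last offset where a full
    window fits; trailing samples that do not fill a window are discarded.
    A trial shorter than ``w`` yields no windows.
    """
    if w < 1 or s < 1:
        raise ParameterError(f"window {w} and stride {s} must be >= 1")
    T = rec.n_samples
    out = []
    for t in range(0, T - w + 1, s):
        out.append(
            Segment(
                window=rec.samples[:, t : t + w],
                labels=rec.labels,
                trial_id=rec.trial_id,
                start=t,
            )
        )
    return out


def segment_dataset(recs: Iterable[EEGRecording], w: int = 1000, s: int = 500) -> list:
    segs = []
    for rec in recs:
        segs.extend(sliding_windows(rec, w, s))
    return segs


@dataclass
class SplitAssignment:
    """Mapping of trial_id (or segment key) to one of train/val/test."""

    mapping: dict
    fractions: tuple
    seed: int
    granularity: str = "trial"

    def split_of(self, seg: Segment) -> str:
        key = seg.trial_id if self.granularity == "trial" else (seg.trial_id, seg.start)
        return self.mapping[key]

    def select(self, segments: Sequence[Segment], split: str) -> list:
        return [s for s in segments if self.split_of(s) == split]

    def to_frame(self) -> pd.DataFrame:
        if self.granularity == "trial":
            rows = [{"trial_id": k, "split": v} for k, v in self.mapping.items()]
        else:
            rows = [
                {"trial_id": k[0], "start": k[1], "split": v}
                for k, v in self.mapping.items()
            ]
        return pd.DataFrame(rows)


def _allocate(keys: list, fractions, quota, counts, rng, force_first_train: bool):
    """Assign keys to splits, tracking global quota deficits (Bresenham-style)."""
    names = ("train", "val", "test")
    out = {}
    for j, key in enumerate(keys):
        for name, f in zip(names, fractions):
            quota[name] += f
        if force_first_train and j == 0:
            choice = "train"
        else:
            deficit = {n: quota[n] - counts[n] for n in names}
            choice = max(names, key=lambda n: (deficit[n], fractions[names.index(n)]))
        counts[choice] += 1
        out[key] = choice
    return out


def make_splits(
    segments: Sequence[Segment],
    fractions: tuple = (0.7, 0.15, 0.15),
    seed: int = 0,
    granularity: str = "trial",
) -> SplitAssignment:
    """Partition segments into train/val/test without window leakage.

    The assignment depends only on the *set* of trial ids, the fractions and
    the seed — not on segment order.  Trials are grouped by subject and
    allocated per subject so every subject contributes at least one training
    trial; global split sizes track the requested fractions via accumulated
    quotas.
    """
    if granularity not in ("trial", "window"):
        raise ParameterError(f"granularity must be 'trial' or 'window', got {granularity!r}")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ParameterError(f"fractions must be three non-negative reals, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError(f"fractions must sum to 1, got sum {sum(fractions)}")

    by_subject: dict = {}
    for seg in segments:
        by_subject.setdefault(seg.subject_id, set()).add(seg.trial_id)

    n_splits = sum(1 for f in fractions if f > 0)
    rng = np.random.default_rng(seed)
    mapping: dict = {}
    quota = {"train": 0.0, "val": 0.0, "test": 0.0}
    counts = {"train": 0, "val": 0, "test": 0}
    for subject in sorted(by_subject):
        trials = sorted(by_subject[subject])
        order = [trials[i] for i in rng.permutation(len(trials))]
        if len(trials) < 2 and n_splits > 1:
            warnings.warn(
                f"subject {subject!r} has {len(trials)} trial(s); kept whole in train",
                stacklevel=2,
            )
            for t in order:
                mapping[t] = "train"
                counts["train"] += 1
                for name, f in zip(("train", "val", "test"), fractions):
                    quota[name] += f
            continue
        mapping.update(
            _allocate(order, fractions, quota, counts, rng, force_first_train=True)
        )

    if granularity == "window":
        # reassign each window independently, ignoring trial grouping
        keys = sorted({(s.trial_id, s.start) for s in segments})
        order = [keys[i] for i in rng.permutation(len(keys))]
        quota = {"train": 0.0, "val": 0.0, "test": 0.0}
        counts = {"train": 0, "val": 0, "test": 0}
        mapping = _allocate(order, fractions, quota, counts, rng, force_first_train=False)

    return SplitAssignment(mapping=mapping, fractions=fractions, seed=seed, granularity=granularity)


def zscore_window(window: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Standardize each channel of one window to zero mean, unit variance."""
    mu = window.mean(axis=-1, keepdims=True)
    sd = window.std(axis=-1, keepdims=True)
    return (window - mu) / (sd + eps)


@dataclass
class LabelVocab:
    """Stable label-to-index maps for the three tasks.

    Subjects are indexed by sorted identifier; language and device use the
    fixed orders ``(native, non_native)`` and ``(in_ear, bone)``.
    """

    subjects: tuple

    @classmethod
    def from_segments(cls, segments: Iterable[Segment]) -> "LabelVocab":
        return cls(subjects=tuple(sorted({s.subject_id for s in segments})))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def encode(self, seg: Segment) -> tuple:
        return (
            self.subjects.index(seg.subject_id),
            LANGUAGES.index(seg.language),
            DEVICES.index(seg.device),
        )


def segments_to_arrays(
    segments: Sequence[Segment],
    vocab: LabelVocab,
    normalize: bool = True,
    dtype=np.float32,
):
    """Stack segments into a batch array and integer label arrays.

    Returns ``(X, y)`` with ``X`` of shape (n, channels, w) and ``y`` a dict
    with keys ``bio``, ``lang``, ``dev``.
    """
    if not segments:
        raise ParameterError("no segments to convert")
    subj_index = {s: i for i, s in enumerate(vocab.subjects)}
    X = np.empty((len(segments), *segments[0].window.shape), dtype=dtype)
    y = {
        "bio": np.empty(len(segments), dtype=np.int64),
        "lang": np.empty(len(segments), dtype=np.int64),
        "dev": np.empty(len(segments), dtype=np.int64),
    }
    for i, seg in enumerate(segments):
        win = zscore_window(seg.window) if normalize else seg.window
        X[i] = win
        y["bio"][i] = subj_index[seg.subject_id]
        y["lang"][i] = LANGUAGES.index(seg.language)
        y["dev"][i] = DEVICES.index(seg.device)
    return X, y
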