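"""Core data containers: EEG recordings and dataset manifests.

An :class:`EEGRecording` is one trial (or session) of multichannel EEG with
its three labels: the subject who produced it, the language of the auditory
stimulus (native vs non-native), and the delivery modality (in-ear vs bone
conduction).  Samples are stored channels-first, shape ``(C, T)``; time is
always the last axis so per-channel signal processing can operate on
``axis=-1`` without transposes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError, ParseError

LANGUAGES = ("native", "non_native")
DEVICES = ("in_ear", "bone")

#: Manifest columns required by :func:`read_manifest`.
MANIFEST_COLUMNS = ("path", "subject_id", "language", "device", "trial_id")


@dataclass
class EEGRecording:
    """One labelled EEG trial, channels-first.

    Parameters
    ----------
    subject_id : str
        Identifier of the participant, e.g. ``"s03"``.
    language : str
        Stimulus language condition, ``"native"`` or ``"non_native"``.
    device : str
        Delivery modality, ``"in_ear"`` or ``"bone"``.
    trial_id : str
        Unique identifier of this trial within its dataset.
    sampling_rate : float
        Sampling frequency in Hz, strictly positive.
    channel_names : sequence of str
        Ordered electrode names, one per row of ``samples``.
    samples : ndarray, shape (n_channels, n_samples)
        Voltage time series.
    """

    subject_id: str
    language: str
    device: str
    trial_id: str
    sampling_rate: float
    channel_names: tuple
    samples: np.ndarray

    def __post_init__(self):
        self.channel_names = tuple(str(c) for c in self.channel_names)
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ParameterError(
                f"samples must be 2-D (channels, time); got shape {self.samples.shape}"
            )
        if len(self.channel_names) != self.samples.shape[0]:
            raise ConsistencyError(
                f"{len(self.channel_names)} channel names but "
                f"{self.samples.shape[0]} sample rows"
            )
        if self.samples.shape[1] < 1:
            raise ParameterError("recording must contain at least one sample")
        if not self.sampling_rate > 0:
            raise ParameterError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.language not in LANGUAGES:
            raise ParameterError(
                f"language must be one of {LANGUAGES}, got {self.language!r}"
            )
        if self.device not in DEVICES:
            raise ParameterError(f"device must be one of {DEVICES}, got {self.device!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def labels(self) -> tuple:
        """The (subject_id, language, device) label triplet."""
        return (self.subject_id, self.language, self.device)

    def with_samples(self, samples: np.ndarray, sampling_rate: float | None = None):
        """Return a copy carrying new samples (labels and metadata retained)."""
        return replace(
            self,
            samples=samples,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
        )


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest (CSV or TSV by extension).

    The manifest lists one row per trial with columns
    ``path, subject_id, language, device, trial_id``.  Each
    (subject, language, device, trial) combination must be unique.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"manifest {path} is missing columns {missing}")
    key_cols = ["subject_id", "language", "device", "trial_id"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        first = df.loc[dup.idxmax(), key_cols].tolist()
        raise ConsistencyError(f"duplicate manifest entry {tuple(first)}")
    if df["trial_id"].duplicated().any():
        raise ConsistencyError("trial_id values must be unique within a manifest")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)
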