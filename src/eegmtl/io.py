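"""Reading, filtering, resampling and aligning EEG recordings.

Supports two on-disk formats: plain CSV (header row of channel names, one
sample per row — the format the synthetic generator writes) and EDF via
``mne`` when it is installed.  Preprocessing follows common auditory-EEG
practice: zero-phase Butterworth band-pass, polyphase anti-aliased
downsampling, and truncation of all trials to the shortest common duration
so that every trial yields the same sliding-window grid.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ChannelError, ConsistencyError, ParameterError, ParseError
from .records import EEGRecording, read_manifest

__all__ = [
    "read_recording",
    "write_recording_csv",
    "load_dataset",
    "bandpass_filter",
    "downsample",
    "align_trials",
    "preprocess_dataset",
    "save_dataset_cache",
    "load_dataset_cache",
]

#: The four channels used throughout: right parietal, central midline,
#: right frontal and left temporal sites of the 10-20 system.
DEFAULT_CHANNELS = ("P4", "Cz", "F8", "T7")


def _read_csv_samples(path) -> tuple[list, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = int(bad.idxmax()) if bad.any() else int(coerced.isna().idxmax())
            raise ParseError(
                f"non-numeric value in column {col!r} at data row {row} of {path}"
            )
    return list(df.columns), df.to_numpy(dtype=np.float64).T


def _read_edf_samples(path) -> tuple[list, np.ndarray, float]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading EDF files requires the optional dependency 'mne'"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return list(raw.ch_names), raw.get_data(), float(raw.info["sfreq"])


def read_recording(
    path,
    manifest_row: Mapping,
    channel_subset: Sequence[str] = DEFAULT_CHANNELS,
    sampling_rate: float | None = None,
) -> EEGRecording:
    """Read one trial from disk and attach its labels.

    Parameters
    ----------
    path : path-like
        A ``.csv`` file (header = channel names, one sample per row) or an
        ``.edf`` file.
    manifest_row : mapping
        Must provide ``subject_id``, ``language``, ``device``, ``trial_id``
        and, for CSV input, ``sampling_rate`` (unless given explicitly).
    channel_subset : sequence of str
        Channels to retain, in the requested order.
    sampling_rate : float, optional
        Overrides the manifest / file header rate (required for CSV when the
        manifest has no ``sampling_rate`` column).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if path.suffix.lower() == ".edf":
        names, data, fs = _read_edf_samples(path)
        if sampling_rate is not None:
            fs = float(sampling_rate)
    else:
        names, data = _read_csv_samples(path)
        if sampling_rate is not None:
            fs = float(sampling_rate)
        elif "sampling_rate" in manifest_row and manifest_row["sampling_rate"] is not None:
            fs = float(manifest_row["sampling_rate"])
        else:
            raise ParameterError(
                f"sampling_rate required for CSV recording {path} "
                "(manifest column or explicit argument)"
            )
    index = {name: i for i, name in enumerate(names)}
    rows = []
    for ch in channel_subset:
        if ch not in index:
            raise ChannelError(f"channel {ch!r} not present in {path} (has {names})")
        rows.append(index[ch])
    return EEGRecording(
        subject_id=str(manifest_row["subject_id"]),
        language=str(manifest_row["language"]),
        device=str(manifest_row["device"]),
        trial_id=str(manifest_row["trial_id"]),
        sampling_rate=fs,
        channel_names=tuple(channel_subset),
        samples=data[rows],
    )


def write_recording_csv(rec: EEGRecording, path) -> None:
    """Write a recording as CSV (channels as columns, one sample per row).

    Floats are printed with Python's shortest round-trip repr, so a
    read-back reproduces the samples bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write(",".join(rec.channel_names) + "\n")
        for row in rec.samples.T:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def load_dataset(
    manifest_path,
    channel_subset: Sequence[str] = DEFAULT_CHANNELS,
    sampling_rate: float | None = None,
) -> list:
    """Read every trial listed in a manifest. Paths are resolved relative to it."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    recs = []
    for row in df.to_dict("records"):
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        recs.append(read_recording(p, row, channel_subset, sampling_rate))
    return recs


def bandpass_filter(
    rec: EEGRecording, low_hz: float = 0.5, high_hz: float = 45.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective order
    and leaves component phases untouched, which preserves evoked-response
    latencies.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.sampling_rate, output="sos")
    return rec.with_samples(signal.sosfiltfilt(sos, rec.samples, axis=-1))


def downsample(rec: EEGRecording, target_rate: float = 200.0) -> EEGRecording:
    """Resample to ``target_rate`` with polyphase anti-alias filtering."""
    if target_rate > rec.sampling_rate:
        raise ParameterError(
            f"target_rate {target_rate} exceeds sampling_rate {rec.sampling_rate}"
        )
    if target_rate == rec.sampling_rate:
        return rec.with_samples(rec.samples.copy())
    ratio = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    out = signal.resample_poly(rec.samples, ratio.numerator, ratio.denominator, axis=-1)
    return rec.with_samples(out, sampling_rate=rec.sampling_rate * ratio)


def align_trials(recs: Sequence[EEGRecording]) -> list:
    """Truncate every trial to the shortest length in the set.

    The leading samples are kept: auditory evoked responses are locked to
    stimulus onset, so the head of the trial carries the signal of interest.
    """
    recs = list(recs)
    if not recs:
        raise ParameterError("align_trials requires a non-empty list")
    n_ch = {r.n_channels for r in recs}
    if len(n_ch) != 1:
        raise ConsistencyError(f"mixed channel counts in trial set: {sorted(n_ch)}")
    rates = {r.sampling_rate for r in recs}
    if len(rates) != 1:
        raise ConsistencyError(f"mixed sampling rates in trial set: {sorted(rates)}")
    n = min(r.n_samples for r in recs)
    return [r.with_samples(r.samples[:, :n]) for r in recs]


def preprocess_dataset(
    recs: Iterable[EEGRecording],
    low_hz: float = 0.5,
    high_hz: float = 45.0,
    order: int = 4,
    target_rate: float = 200.0,
    filter_enabled: bool = True,
) -> list:
    """Band-pass, downsample and align a set of trials (the standard chain)."""
    out = []
    for rec in recs:
        if filter_enabled:
            rec = bandpass_filter(rec, low_hz, high_hz, order)
        if target_rate < rec.sampling_rate:
            rec = downsample(rec, target_rate)
        out.append(rec)
    return align_trials(out)


def save_dataset_cache(recs: Sequence[EEGRecording], path) -> None:
    """Persist preprocessed trials to one ``.npz`` container.

    One array per trial_id plus a JSON metadata table carrying labels,
    sampling rate and channel names.
    """
    meta = {
        "channel_names": list(recs[0].channel_names) if recs else [],
        "trials": [
            {
                "trial_id": r.trial_id,
                "subject_id": r.subject_id,
                "language": r.language,
                "device": r.device,
                "sampling_rate": r.sampling_rate,
            }
            for r in recs
        ],
    }
    arrays = {f"trial_{r.trial_id}": r.samples for r in recs}
    np.savez_compressed(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_dataset_cache(path) -> list:
    with np.load(path) as z:
        meta = json.loads(z["_meta"].tobytes().decode())
        recs = []
        for t in meta["trials"]:
            recs.append(
                EEGRecording(
                    subject_id=t["subject_id"],
                    language=t["language"],
                    device=t["device"],
                    trial_id=t["trial_id"],
                    sampling_rate=t["sampling_rate"],
                    channel_names=tuple(meta["channel_names"]),
                    samples=z[f"trial_{t['trial_id']}"],
                )
            )
    return recs
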