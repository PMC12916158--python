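import numpy as np
import pytest

from eegmtl import EEGRecording, SynthConfig, generate_dataset
from eegmtl.network import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_synth_config():
    """A few-second, few-subject dataset that generates in well under a second."""
    return SynthConfig(
        n_subjects=3,
        n_trials_per_cell=2,
        trial_length=600,
        sampling_rate=200.0,
        seed=7,
    )


@pytest.fixture
def tiny_dataset(tiny_synth_config):
    return generate_dataset(tiny_synth_config)


@pytest.fixture
def small_model_config():
    """A narrow network for fast unit tests."""
    return ModelConfig(
        in_channels=4,
        conv_channels=(8, 16),
        d_model=16,
        n_layers=2,
        n_heads=2,
        ffn_dim=32,
        dropout=0.0,
        head_hidden=8,
        n_subjects=3,
        max_seq_len=300,
    )


def make_recording(
    samples,
    sampling_rate=200.0,
    subject="s01",
    language="native",
    device="in_ear",
    trial="t00",
    channels=None,
):
    samples = np.asarray(samples)
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(samples.shape[0]))
    return EEGRecording(
        subject_id=subject,
        language=language,
        device=device,
        trial_id=trial,
        sampling_rate=sampling_rate,
        channel_names=channels,
        samples=samples,
    )
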