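"""Standard study configurations.

Two named setups are used throughout the test suite and the acceptance
script:

* :func:`default_study` — the full desk-scale study: 20 subjects x
  2 languages x 2 devices x 6 trials of 10 s at 200 Hz, windows of 1000
  samples at stride 500, the reference architecture (d=64, L=2, H=4) and
  the reference training configuration (Adam, lr 1e-4, step decay 0.5
  every 5 epochs, max 20 epochs, batch 16).
* :func:`variant_benchmark` — a reduced setup for comparing many
  architecture variants over several seeds on one CPU: 20 subjects x
  2 x 2 x 2 trials of 10 s at 100 Hz, the same 5 s windows with 50%
  overlap (w = 500, stride 250), a narrower network (d = 32) and a faster
  optimization (lr 1e-3, 20 epochs); the smaller model and the several
  times fewer gradient steps motivate the proportionally larger learning
  rate.
"""

from __future__ import annotations

from .evaluation import BenchmarkTable, run_benchmark
from .model import MultiTaskEEGModel
from .network import ModelConfig
from .segmentation import LabelVocab, make_splits, segment_dataset
from .synthetic import SynthConfig, generate_dataset
from .training import TrainConfig

__all__ = [
    "default_study",
    "variant_benchmark",
    "run_default_study",
    "run_variant_benchmark",
]


def default_study(seed: int = 1):
    """Configs for the full study; returns (SynthConfig, ModelConfig, TrainConfig)."""
    synth = SynthConfig(seed=seed)
    model = ModelConfig(in_channels=len(synth.channels), n_subjects=synth.n_subjects)
    train = TrainConfig(seed=seed)
    return synth, model, train


#: window length / stride of the reduced benchmark: the same 5 s windows
#: with 50% overlap as the default study, at its 100 Hz sampling rate
BENCHMARK_WINDOW = 500
BENCHMARK_STRIDE = 250


def variant_benchmark(seed: int = 1):
    """Configs for the reduced variant-comparison benchmark."""
    synth = SynthConfig(
        n_trials_per_cell=2, sampling_rate=100.0, trial_length=1000, seed=seed
    )
    model = ModelConfig(
        in_channels=len(synth.channels),
        conv_channels=(16, 32),
        d_model=32,
        n_heads=4,
        ffn_dim=128,
        head_hidden=32,
        n_subjects=synth.n_subjects,
        max_seq_len=160,
    )
    train = TrainConfig(lr=1e-3, epochs=30, step_size=8, seed=seed)
    return synth, model, train


def run_default_study(seed: int = 1, variant: str = "full", verbose: bool = False):
    """Generate the default study, train one variant, return the Results."""
    synth, mcfg, tcfg = default_study(seed)
    recs = generate_dataset(synth)
    model = MultiTaskEEGModel.from_recordings(
        recs, window=1000, stride=500, seed=seed,
        model_config=mcfg, train_config=tcfg,
    )
    return model.fit(variant, verbose=verbose)


def run_variant_benchmark(
    variants=("full", "no_transformer", "no_conv", "sc_sc", "stt"),
    seeds=(1, 2, 3),
    data_seed: int = 1,
) -> BenchmarkTable:
    """Train every variant under identical splits for each seed."""
    synth, mcfg, tcfg = variant_benchmark(data_seed)
    recs = generate_dataset(synth)
    segs = segment_dataset(recs, BENCHMARK_WINDOW, BENCHMARK_STRIDE)
    splits = make_splits(segs, (0.7, 0.15, 0.15), seed=data_seed)
    parts = {name: splits.select(segs, name) for name in ("train", "val", "test")}
    vocab = LabelVocab.from_segments(segs)
    return run_benchmark(list(variants), parts, list(seeds), mcfg, tcfg, vocab)
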