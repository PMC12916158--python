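"""Experiment orchestration: config files, run records, reports.

A single YAML config drives every subcommand; its sections mirror the
configuration dataclasses field-for-field::

    seed: 1
    synth:        { n_subjects: 20, n_trials_per_cell: 6, ... }
    segmentation: { window: 1000, stride: 500, fractions: [0.7, 0.15, 0.15], ... }
    model:        { d_model: 64, n_layers: 2, ... }
    train:        { lr: 1.0e-4, epochs: 20, ... }
    benchmark:    { variants: [full, stt, sc_sc], seeds: [1, 2, 3] }

Every command writes its artifacts into a run directory named by timestamp
and seed, together with a ``run_record.json`` capturing the config
snapshot, seed, a content hash of the inputs, and the emitted paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as data_io
from .errors import ConfigError, DependencyError, ParameterError
from .evaluation import BenchmarkTable, EvalReport, evaluate, run_benchmark
from .model import MultiTaskEEGModel
from .network import ModelConfig, load_checkpoint, save_checkpoint
from .segmentation import LabelVocab, make_splits, segment_dataset
from .synthetic import SynthConfig, write_dataset
from .training import TrainConfig, set_global_seed, train

logger = logging.getLogger("eegmtl")

COMMANDS = ("simulate", "preprocess", "train", "evaluate", "benchmark", "ablate")


@dataclass
class SegmentationConfig:
    window: int = 1000
    stride: int = 500
    fractions: tuple = (0.7, 0.15, 0.15)
    granularity: str = "trial"
    normalize: bool = True

    def __post_init__(self):
        self.fractions = tuple(float(f) for f in self.fractions)
        if self.window < 1 or self.stride < 1:
            raise ConfigError("window and stride must be >= 1")


@dataclass
class PreprocessConfig:
    channels: tuple = ("P4", "Cz", "F8", "T7")
    low_hz: float = 0.5
    high_hz: float = 45.0
    filter_order: int = 4
    target_rate: float = 200.0
    filter_enabled: bool = True

    def __post_init__(self):
        self.channels = tuple(self.channels)


@dataclass
class BenchmarkConfig:
    variants: tuple = ("full", "stt", "sc_sc")
    seeds: tuple = (1, 2, 3)

    def __post_init__(self):
        self.variants = tuple(self.variants)
        self.seeds = tuple(int(s) for s in self.seeds)


@dataclass
class ExperimentConfig:
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    variant: str = "full"

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "synth": SynthConfig,
    "preprocess": PreprocessConfig,
    "segmentation": SegmentationConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "benchmark": BenchmarkConfig,
}


def load_config(path=None, overrides: dict | None = None) -> ExperimentConfig:
    """Parse and validate a YAML config; collect *all* invalid keys at once."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    if overrides:
        raw = _deep_merge(raw, overrides)

    invalid = []
    kwargs = {}
    for key, value in raw.items():
        if key in ("seed", "variant"):
            kwargs[key] = value
        elif key in _SECTIONS:
            cls = _SECTIONS[key]
            known = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - known
            invalid.extend(f"{key}.{k}" for k in sorted(bad))
            kwargs[key] = {k: v for k, v in value.items() if k in known}
        else:
            invalid.append(key)
    if invalid:
        raise ConfigError(f"invalid config keys: {invalid}")

    try:
        sections = {
            name: _SECTIONS[name](**kwargs.get(name, {})) for name in _SECTIONS
        }
        cfg = ExperimentConfig(
            seed=int(kwargs.get("seed", 0)),
            variant=str(kwargs.get("variant", "full")),
            **sections,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    # propagate the experiment seed into sections that default to 0
    if "seed" not in raw.get("synth", {}):
        cfg.synth = dataclasses.replace(cfg.synth, seed=cfg.seed)
    if "seed" not in raw.get("train", {}):
        cfg.train = dataclasses.replace(cfg.train, seed=cfg.seed)
    return cfg


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunRecord:
    """Provenance of one pipeline run."""

    command: str
    seed: int
    config: dict
    input_hash: str
    run_dir: str
    started: str
    artifacts: list = field(default_factory=list)
    finished: str = ""

    def add(self, path) -> Path:
        self.artifacts.append(str(path))
        return Path(path)

    def save(self) -> Path:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        out = Path(self.run_dir) / "run_record.json"
        out.write_text(json.dumps(asdict(self), indent=2))
        return out


def _hash_config(cfg: ExperimentConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _make_run_dir(outdir, command: str, seed: int) -> Path:
    stamp = time.strftime("%Y%m%d-%H%M%S")
    run_dir = Path(outdir) / f"{stamp}_{command}_seed{seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    return run_dir


def _prepare_segments(cfg: ExperimentConfig, workdir: Path):
    cache = workdir / "preprocessed.npz"
    if not cache.exists():
        raise DependencyError(
            f"missing preprocessed cache {cache}; run the 'preprocess' command first"
        )
    recs = data_io.load_dataset_cache(cache)
    segs = segment_dataset(recs, cfg.segmentation.window, cfg.segmentation.stride)
    splits = make_splits(
        segs, cfg.segmentation.fractions, cfg.seed, cfg.segmentation.granularity
    )
    vocab = LabelVocab.from_segments(segs)
    parts = {name: splits.select(segs, name) for name in ("train", "val", "test")}
    return segs, splits, parts, vocab


def parse_overrides(pairs) -> dict:
    """Turn ``section.key=value`` strings into a nested override mapping."""
    out: dict = {}
    for pair in pairs or ():
        if "=" not in pair:
            raise ConfigError(f"override {pair!r} is not of the form section.key=value")
        key, _, raw = pair.partition("=")
        value = yaml.safe_load(raw)
        node = out
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return out


def run_experiment(
    config_path,
    command: str,
    outdir="runs",
    seed: int | None = None,
    overrides: dict | None = None,
) -> tuple:
    """Execute one pipeline command; returns (exit_status, RunRecord)."""
    if command not in COMMANDS:
        raise ParameterError(f"unknown command {command!r}; expected one of {COMMANDS}")
    cfg = load_config(config_path, overrides)
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
        cfg.synth = dataclasses.replace(cfg.synth, seed=int(seed))
        cfg.train = dataclasses.replace(cfg.train, seed=int(seed))
    set_global_seed(cfg.seed)
    outdir = Path(outdir)
    run_dir = _make_run_dir(outdir, command, cfg.seed)
    record = RunRecord(
        command=command,
        seed=cfg.seed,
        config=cfg.to_dict(),
        input_hash=_hash_config(cfg),
        run_dir=str(run_dir),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    logger.info("command=%s seed=%d run_dir=%s", command, cfg.seed, run_dir)

    workdir = outdir / "work"
    workdir.mkdir(parents=True, exist_ok=True)

    if command == "simulate":
        data_dir = workdir / "data"
        manifest = write_dataset(cfg.synth, data_dir)
        record.add(manifest)
        logger.info("wrote %d trials to %s", cfg.synth.n_trials, data_dir)

    elif command == "preprocess":
        manifest = workdir / "data" / "manifest.csv"
        if not manifest.exists():
            raise DependencyError(
                f"missing manifest {manifest}; run the 'simulate' command first "
                "(or point it at real data)"
            )
        recs = data_io.load_dataset(manifest, cfg.preprocess.channels)
        recs = data_io.preprocess_dataset(
            recs,
            cfg.preprocess.low_hz,
            cfg.preprocess.high_hz,
            cfg.preprocess.filter_order,
            cfg.preprocess.target_rate,
            cfg.preprocess.filter_enabled,
        )
        cache = workdir / "preprocessed.npz"
        data_io.save_dataset_cache(recs, cache)
        record.add(cache)
        logger.info("cached %d preprocessed trials", len(recs))

    elif command == "train":
        segs, splits, parts, vocab = _prepare_segments(cfg, workdir)
        record.add(run_dir / "split_manifest.csv")
        splits.to_frame().to_csv(run_dir / "split_manifest.csv", index=False)
        mcfg = dataclasses.replace(
            cfg.model,
            in_channels=len(cfg.preprocess.channels),
            n_subjects=vocab.n_subjects,
        )
        model = MultiTaskEEGModel(
            segs, splits=splits, model_config=mcfg, train_config=cfg.train, seed=cfg.seed
        )
        res = model.fit(cfg.variant, verbose=True)
        ckpt = workdir / "checkpoint.npz"
        save_checkpoint(res.network, ckpt)
        record.add(ckpt)
        res.history_frame().to_csv(record.add(run_dir / "history.csv"), index=False)
        (run_dir / "history.json").write_text(
            json.dumps(res.history.epochs, indent=2, default=float)
        )
        record.add(run_dir / "history.json")
        if res.report is not None:
            write_report(record, [res.report])
        (run_dir / "summary.txt").write_text(res.summary() + "\n")
        record.add(run_dir / "summary.txt")

    elif command == "evaluate":
        ckpt = workdir / "checkpoint.npz"
        if not ckpt.exists():
            raise DependencyError(
                f"missing checkpoint {ckpt}; run the 'train' command first"
            )
        net = load_checkpoint(ckpt)
        _, _, parts, vocab = _prepare_segments(cfg, workdir)
        report = evaluate(
            net, parts["test"], vocab, split="test", seed=cfg.seed,
            normalize=cfg.segmentation.normalize,
        )
        write_report(record, [report])

    elif command in ("benchmark", "ablate"):
        _, _, parts, vocab = _prepare_segments(cfg, workdir)
        variants = (
            cfg.benchmark.variants
            if command == "benchmark"
            else ("full", "no_transformer", "no_conv")
        )
        mcfg = dataclasses.replace(
            cfg.model,
            in_channels=len(cfg.preprocess.channels),
            n_subjects=vocab.n_subjects,
        )
        table = run_benchmark(variants, parts, cfg.benchmark.seeds, mcfg, cfg.train, vocab)
        write_report(record, [table])

    record.save()
    return 0, record


def write_report(record: RunRecord, reports: list) -> list:
    """Write JSON/CSV and a markdown summary for a list of report objects."""
    run_dir = Path(record.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    md = [f"# Run report", "", f"- command: {record.command}", f"- seed: {record.seed}",
          f"- input hash: {record.input_hash}", ""]
    if not reports:
        md.append("No reports were produced by this run.")
    for i, rep in enumerate(reports):
        if isinstance(rep, EvalReport):
            base = run_dir / f"eval_{rep.split}_{i}"
            p = base.with_suffix(".json")
            p.write_text(json.dumps(rep.to_dict(), indent=2))
            paths.append(record.add(p))
            for task, cm in rep.confusion.items():
                cp = base.parent / f"{base.name}_confusion_{task}.csv"
                pd.DataFrame(cm).to_csv(cp, index=False)
                paths.append(record.add(cp))
            md.append(f"## Evaluation ({rep.split}, seed {rep.seed}, variant {rep.variant})")
            md.append("")
            for task, acc in rep.accuracy.items():
                md.append(f"- {task}: {acc:.1%} over {rep.n_segments} segments")
            md.append("")
        elif isinstance(rep, BenchmarkTable):
            base = run_dir / f"benchmark_{i}"
            df = rep.to_frame()
            df.to_csv(base.with_suffix(".csv"), index=False)
            paths.append(record.add(base.with_suffix(".csv")))
            base.with_suffix(".json").write_text(df.to_json(orient="records", indent=2))
            paths.append(record.add(base.with_suffix(".json")))
            md.append(f"## Benchmark over seeds {list(rep.seeds)}")
            md.append("")
            md.append(df.to_string(index=False))
            md.append("")
    summary = run_dir / "report.md"
    summary.write_text("\n".join(md) + "\n")
    paths.append(record.add(summary))
    return paths
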