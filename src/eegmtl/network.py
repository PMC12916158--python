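"""The conv-transformer multi-task EEG network and its variants.

The full architecture is:

1. **Temporal conv encoder** — two strided 1-D conv blocks (kernel 5,
   stride 2, each followed by batch-norm and ReLU) that turn a
   ``(B, C, w)`` window into a ``(B, T', d)`` feature sequence with
   ``T' = w / 4`` under the default padding of 2.
2. **Transformer encoder** — a learnable classification (CLS) token is
   prepended, learnable positional embeddings added, and L post-norm
   encoder layers with H attention heads are applied; the output state of
   the CLS token is the shared representation ``h_cls``.
3. **Task heads** — three two-layer MLPs map ``h_cls`` to logits for
   subject identity (n_subjects classes), stimulus language (2) and
   delivery modality (2).

Variants used for baselines and ablations:

====================  =====================================================
``full``              conv -> transformer -> three heads
``no_transformer``    conv -> chunked temporal average pooling (the feature
                      sequence averaged within 10 equal chunks, flattened)
                      -> three heads; the conv output is forwarded directly
                      to the classifiers with only a bounded reduction of
                      the time axis
``sc_sc``             identical skeleton to ``no_transformer``; kept as a
                      separately named baseline (shared CNN + separate
                      classifiers)
``no_conv``           non-overlapping temporal patches linearly projected
                      to d -> transformer -> three heads
``stt_bio/lang/dev``  the full skeleton with a single task head
====================  =====================================================
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import ConfigError, ParameterError, VariantInterfaceError
from .nn.attention import softmax

__all__ = [
    "ModelConfig",
    "VariantSpec",
    "VARIANTS",
    "TASKS",
    "ForwardOutput",
    "MultiTaskNet",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

TASKS = ("bio", "lang", "dev")

VARIANTS = ("full", "stt_bio", "stt_lang", "stt_dev", "sc_sc", "no_transformer", "no_conv")


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference design)."""

    in_channels: int = 4
    conv_kernel: int = 5
    conv_stride: int = 2
    conv_channels: tuple = (32, 64)
    conv_padding: int = 2
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    ffn_dim: int = 256
    dropout: float = 0.1
    head_hidden: int = 64
    n_subjects: int = 20
    use_positional: bool = True
    patch_size: int = 4       # temporal patch length for the no_conv variant
    pool_chunks: int = 10     # temporal chunks kept by the no_transformer head input
    max_seq_len: int = 1024   # capacity of the positional table

    def __post_init__(self):
        self.conv_channels = tuple(self.conv_channels)
        if self.d_model % self.n_heads != 0:
            raise ConfigError(
                f"d_model {self.d_model} must be divisible by n_heads {self.n_heads}"
            )
        if self.conv_channels[-1] != self.d_model:
            raise ConfigError(
                f"last conv width {self.conv_channels[-1]} must equal d_model {self.d_model}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")

    def head_width(self, task: str) -> int:
        if task == "bio":
            return self.n_subjects
        if task in ("lang", "dev"):
            return 2
        raise ParameterError(f"unknown task {task!r}; expected one of {TASKS}")


@dataclass(frozen=True)
class VariantSpec:
    """Which architecture variant to build."""

    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")

    @property
    def tasks(self) -> tuple:
        if self.variant.startswith("stt_"):
            return (self.variant[4:],)
        return TASKS

    @property
    def use_transformer(self) -> bool:
        return self.variant not in ("no_transformer", "sc_sc")

    @property
    def use_conv(self) -> bool:
        return self.variant != "no_conv"


class ForwardOutput:
    """Per-task logits plus the shared representation of one forward pass.

    Accessing the logits of a task the variant does not expose raises
    :class:`VariantInterfaceError`.
    """

    def __init__(self, logits: dict, h_cls: np.ndarray):
        self._logits = logits
        self.h_cls = h_cls

    @property
    def tasks(self) -> tuple:
        return tuple(self._logits)

    def logits(self, task: str) -> np.ndarray:
        if task not in self._logits:
            raise VariantInterfaceError(
                f"this variant exposes {tuple(self._logits)}, not {task!r}"
            )
        return self._logits[task]

    def probabilities(self, task: str) -> np.ndarray:
        return softmax(self.logits(task), axis=-1)

    @property
    def logits_bio(self) -> np.ndarray:
        return self.logits("bio")

    @property
    def logits_lang(self) -> np.ndarray:
        return self.logits("lang")

    @property
    def logits_dev(self) -> np.ndarray:
        return self.logits("dev")


class _Head(nn.Module):
    """Two-layer MLP: d -> hidden -> K, ReLU between; outputs logits."""

    def __init__(self, d, hidden, k, rng, dtype):
        super().__init__()
        self.fc1 = nn.Linear(d, hidden, rng, dtype)
        self.relu = nn.ReLU()
        self.fc2 = nn.Linear(hidden, k, rng, dtype)

    def forward(self, h):
        return self.fc2(self.relu(self.fc1(h)))

    def backward(self, grad):
        return self.fc1.backward(self.relu.backward(self.fc2.backward(grad)))


class MultiTaskNet(nn.Module):
    """Forward/backward computation for every architecture variant."""

    def __init__(self, config: ModelConfig, variant: VariantSpec = VariantSpec(), seed: int = 0, dtype=np.float32):
        super().__init__()
        self.config = config
        self.variant = variant
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng([seed, 2718281])
        self.dropout_rng = np.random.default_rng([seed, 3141592])
        c = config

        if variant.use_conv:
            c1, c2 = c.conv_channels
            self.conv1 = nn.Conv1d(c.in_channels, c1, c.conv_kernel, c.conv_stride, c.conv_padding, rng, dtype)
            self.bn1 = nn.BatchNorm1d(c1, dtype=dtype)
            self.relu1 = nn.ReLU()
            self.conv2 = nn.Conv1d(c1, c2, c.conv_kernel, c.conv_stride, c.conv_padding, rng, dtype)
            self.bn2 = nn.BatchNorm1d(c2, dtype=dtype)
            self.relu2 = nn.ReLU()
        else:
            self.patch_proj = nn.Linear(c.in_channels * c.patch_size, c.d_model, rng, dtype)

        if variant.use_transformer:
            self.cls = nn.Parameter(rng.normal(0.0, 0.02, (1, c.d_model)).astype(dtype))
            if c.use_positional:
                self.positional = nn.Parameter(
                    rng.normal(0.0, 0.02, (c.max_seq_len, c.d_model)).astype(dtype)
                )
            self.encoder_layers = [
                nn.TransformerEncoderLayer(
                    c.d_model, c.n_heads, c.ffn_dim, c.dropout, rng, self.dropout_rng, dtype
                )
                for _ in range(c.n_layers)
            ]

        head_in = c.d_model if variant.use_transformer else c.d_model * c.pool_chunks
        self.heads = {
            task: _Head(head_in, c.head_hidden, c.head_width(task), rng, dtype)
            for task in variant.tasks
        }
        # expose heads for parameter discovery (dicts are not traversed)
        for task, head in self.heads.items():
            setattr(self, f"head_{task}", head)

        self._cache = {}

    # -- stage: convolutional temporal encoder ----------------------------
    def conv_encode(self, x: np.ndarray) -> np.ndarray:
        """(B, C, w) -> sequence-major features (B, T', d)."""
        z = self.relu1(self.bn1(self.conv1(x)))
        z = self.relu2(self.bn2(self.conv2(z)))
        return z.transpose(0, 2, 1)

    def _conv_backward(self, grad_seq: np.ndarray) -> np.ndarray:
        g = np.ascontiguousarray(grad_seq.transpose(0, 2, 1))
        g = self.conv2.backward(self.bn2.backward(self.relu2.backward(g)))
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(g)))

    def _patch_embed(self, x: np.ndarray) -> np.ndarray:
        B, C, T = x.shape
        P = self.config.patch_size
        if T % P != 0:
            raise ParameterError(f"window length {T} not divisible by patch size {P}")
        n = T // P
        # (B, C, n, P) -> (B, n, C*P): each patch holds all channels
        patches = x.reshape(B, C, n, P).transpose(0, 2, 1, 3).reshape(B, n, C * P)
        self._cache["patch_shape"] = (B, C, T, n, P)
        return self.patch_proj(patches)

    def _patch_backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, T, n, P = self._cache["patch_shape"]
        g = self.patch_proj.backward(grad)
        return g.reshape(B, n, C, P).transpose(0, 2, 1, 3).reshape(B, C, T)

    # -- stage: CLS token and positional embedding -------------------------
    def prepend_cls(self, z: np.ndarray) -> np.ndarray:
        """(B, T', d) -> (B, T'+1, d) with the shared CLS vector at position 0."""
        B, n, d = z.shape
        out = np.empty((B, n + 1, d), dtype=z.dtype)
        out[:, 0, :] = self.cls.data
        out[:, 1:, :] = z
        if self.config.use_positional:
            if n + 1 > self.config.max_seq_len:
                raise ParameterError(
                    f"sequence length {n + 1} exceeds positional capacity {self.config.max_seq_len}"
                )
            out += self.positional.data[: n + 1]
        return out

    def _cls_backward(self, grad: np.ndarray) -> np.ndarray:
        B, n1, d = grad.shape
        if self.config.use_positional:
            self.positional.grad[:n1] += grad.sum(axis=0)
        self.cls.grad += grad[:, 0, :].sum(axis=0, keepdims=True)
        return grad[:, 1:, :]

    # -- stage: transformer encoder ---------------------------------------
    def transformer_encode(self, z: np.ndarray) -> np.ndarray:
        """Run the encoder stack on (B, n, d); return the position-0 state."""
        for layer in self.encoder_layers:
            z = layer(z)
        self._cache["enc_out_shape"] = z.shape
        return z[:, 0, :]

    def _transformer_backward(self, grad_h: np.ndarray) -> np.ndarray:
        g = np.zeros(self._cache["enc_out_shape"], dtype=grad_h.dtype)
        g[:, 0, :] = grad_h
        for layer in reversed(self.encoder_layers):
            g = layer.backward(g)
        return g

    # -- stage: chunked temporal pooling (non-transformer variants) --------
    def _chunk_pool(self, z: np.ndarray) -> np.ndarray:
        """Average the sequence within K equal chunks and flatten to (B, K*d).

        Keeps coarse temporal structure (which part of the window carries
        evoked energy) while bounding the classifier input; trailing tokens
        that do not fill a chunk are dropped.
        """
        B, n, d = z.shape
        K = self.config.pool_chunks
        if n < K:
            raise ParameterError(
                f"sequence of {n} tokens shorter than pool_chunks={K}"
            )
        m = n // K
        pooled = z[:, : K * m, :].reshape(B, K, m, d).mean(axis=2)
        self._cache["pool_shape"] = (B, n, d, K, m)
        return pooled.reshape(B, K * d)

    def _chunk_pool_backward(self, grad: np.ndarray) -> np.ndarray:
        B, n, d, K, m = self._cache["pool_shape"]
        g = np.zeros((B, n, d), dtype=grad.dtype)
        g[:, : K * m, :] = np.repeat(
            grad.reshape(B, K, 1, d) / m, m, axis=2
        ).reshape(B, K * m, d)
        return g

    # -- stage: task heads -------------------------------------------------
    def head_forward(self, h: np.ndarray, task: str) -> np.ndarray:
        if task not in self.heads:
            raise VariantInterfaceError(
                f"variant {self.variant.variant!r} has no {task!r} head"
            )
        return self.heads[task](h)

    # -- full passes -------------------------------------------------------
    def forward(self, x: np.ndarray) -> ForwardOutput:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if self.variant.use_conv:
            z = self.conv_encode(x)
        else:
            z = self._patch_embed(x)
        if self.variant.use_transformer:
            h = self.transformer_encode(self.prepend_cls(z))
        else:
            h = self._chunk_pool(z)
        logits = {task: self.head_forward(h, task) for task in self.variant.tasks}
        return ForwardOutput(logits, h)

    def backward(self, grad_logits: dict) -> None:
        """Backpropagate summed task gradients through the shared trunk."""
        grad_h = None
        for task, g in grad_logits.items():
            gh = self.heads[task].backward(np.ascontiguousarray(g, dtype=self.dtype))
            grad_h = gh if grad_h is None else grad_h + gh
        if self.variant.use_transformer:
            g = self._cls_backward(self._transformer_backward(grad_h))
        else:
            g = self._chunk_pool_backward(grad_h)
        if self.variant.use_conv:
            self._conv_backward(g)
        else:
            self._patch_backward(g)


def build_model(mcfg: ModelConfig, variant: VariantSpec | str = "full", seed: int = 0) -> MultiTaskNet:
    """Construct a network variant with seeded initialization."""
    if isinstance(variant, str):
        variant = VariantSpec(variant)
    return MultiTaskNet(mcfg, variant, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalars in a model."""
    return model.n_parameters()


def save_checkpoint(model: MultiTaskNet, path) -> None:
    """Persist configuration and parameters; reload reproduces eval outputs bit-exactly."""
    meta = {
        "model_config": asdict(model.config),
        "variant": model.variant.variant,
        "seed": model.seed,
        "format_version": 1,
    }
    state = {f"param_{k}": v for k, v in model.state_dict().items()}
    bn_state = {}
    for name, mod in _named_modules(model):
        if isinstance(mod, nn.BatchNorm1d):
            bn_state[f"bnmean_{name}"] = mod.running_mean
            bn_state[f"bnvar_{name}"] = mod.running_var
    np.savez(
        path,
        _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **state,
        **bn_state,
    )


def _named_modules(model: nn.Module, prefix: str = ""):
    for name, value in vars(model).items():
        if isinstance(value, nn.Module):
            yield f"{prefix}{name}", value
            yield from _named_modules(value, f"{prefix}{name}.")
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                if isinstance(item, nn.Module):
                    yield f"{prefix}{name}.{i}", item
                    yield from _named_modules(item, f"{prefix}{name}.{i}.")


def load_checkpoint(path) -> MultiTaskNet:
    with np.load(path) as z:
        meta = json.loads(z["_meta"].tobytes().decode())
        mcfg = ModelConfig(**meta["model_config"])
        model = MultiTaskNet(mcfg, VariantSpec(meta["variant"]), seed=meta["seed"])
        state = {k[6:]: z[k] for k in z.files if k.startswith("param_")}
        model.load_state_dict(state)
        for name, mod in _named_modules(model):
            if isinstance(mod, nn.BatchNorm1d):
                mod.running_mean = z[f"bnmean_{name}"].copy()
                mod.running_var = z[f"bnvar_{name}"].copy()
    return model
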