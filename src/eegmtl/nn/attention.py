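"""Multi-head self-attention and the post-norm transformer encoder layer."""

from __future__ import annotations

import numpy as np

from .core import Module
from .layers import Dropout, LayerNorm, Linear, ReLU


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=axis, keepdims=True)
    return z


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with H parallel heads.

    Queries, keys and values come from one fused projection of the input;
    per-head scores are ``Q Kᵀ / sqrt(d/H)``, row-softmaxed and applied to
    ``V``; head outputs are concatenated and linearly projected back to d.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if d % n_heads != 0:
            raise ValueError(f"model width {d} not divisible by {n_heads} heads")
        self.d, self.H = d, n_heads
        self.hd = d // n_heads
        self.qkv = Linear(d, 3 * d, rng, dtype)
        self.proj = Linear(d, d, rng, dtype)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, n, d = x.shape
        qkv = self.qkv(x).reshape(B, n, 3, self.H, self.hd)
        q, k, v = (qkv[:, :, i].transpose(0, 2, 1, 3) for i in range(3))  # (B,H,n,hd)
        # float() keeps the scale a weak scalar so float32 activations stay float32
        scale = 1.0 / float(np.sqrt(self.hd))
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = softmax(scores, axis=-1)                                   # (B,H,n,n)
        ctx = attn @ v                                                    # (B,H,n,hd)
        out = ctx.transpose(0, 2, 1, 3).reshape(B, n, d)
        self._cache = (q, k, v, attn, scale)
        return self.proj(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        q, k, v, attn, scale = self._cache
        B, H, n, hd = q.shape
        gout = self.proj.backward(grad)
        gctx = np.ascontiguousarray(gout.reshape(B, n, H, hd).transpose(0, 2, 1, 3))
        gattn = gctx @ v.transpose(0, 1, 3, 2)
        gv = attn.transpose(0, 1, 3, 2) @ gctx
        # softmax Jacobian applied row-wise, fused in place on gattn
        row = np.einsum("bhij,bhij->bhi", gattn, attn)
        gattn -= row[..., None]
        gattn *= attn
        gattn *= scale
        gscores = gattn
        gq = gscores @ k
        gk = gscores.transpose(0, 1, 3, 2) @ q
        gqkv = np.empty((B, n, 3, H, hd), dtype=grad.dtype)
        gqkv[:, :, 0] = gq.transpose(0, 2, 1, 3)
        gqkv[:, :, 1] = gk.transpose(0, 2, 1, 3)
        gqkv[:, :, 2] = gv.transpose(0, 2, 1, 3)
        return self.qkv.backward(gqkv.reshape(B, n, 3 * self.d))

    def attention_weights(self) -> np.ndarray:
        """Attention of the most recent forward pass, shape (B, H, n, n)."""
        return self._cache[3]


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: MHSA and position-wise FFN, each wrapped in
    a residual connection followed by layer normalization."""

    def __init__(
        self,
        d: int,
        n_heads: int,
        ffn_dim: int,
        dropout: float,
        rng: np.random.Generator,
        dropout_rng: np.random.Generator,
        dtype=np.float32,
    ):
        super().__init__()
        self.attn = MultiHeadSelfAttention(d, n_heads, rng, dtype)
        self.ln1 = LayerNorm(d, dtype=dtype)
        self.ffn1 = Linear(d, ffn_dim, rng, dtype)
        self.relu = ReLU()
        self.ffn2 = Linear(ffn_dim, d, rng, dtype)
        self.ln2 = LayerNorm(d, dtype=dtype)
        self.drop1 = Dropout(dropout, dropout_rng)
        self.drop2 = Dropout(dropout, dropout_rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x1 = self.ln1(x + self.drop1(self.attn(x)))
        f = self.ffn2(self.relu(self.ffn1(x1)))
        return self.ln2(x1 + self.drop2(f))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.ln2.backward(grad)
        gf = self.drop2.backward(g)
        gx1 = g + self.ffn1.backward(self.relu.backward(self.ffn2.backward(gf)))
        g = self.ln1.backward(gx1)
        ga = self.drop1.backward(g)
        return g + self.attn.backward(ga)
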