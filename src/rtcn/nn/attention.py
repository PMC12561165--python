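"""Multi-head self-attention and the post-norm Transformer encoder layer."""
from __future__ import annotations

import numpy as np

from .core import Module
from .layers import Dropout, LayerNorm, Linear, ReLU


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention; per-head attention maps are kept on
    ``last_attention`` (rows sum to one) for explainability."""

    def __init__(self, d_model, n_heads, rng):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_attention = None

    def _split(self, x):  # (N, L, d) -> (N, h, L, dh)
        n, l, _ = x.shape
        return x.reshape(n, l, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (N, h, L, dh) -> (N, L, d)
        n, h, l, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, l, h * dh)

    def forward(self, x):
        q = self._split(self.wq(x))
        k = self._split(self.wk(x))
        v = self._split(self.wv(x))
        scale = 1.0 / np.sqrt(self.dh)
        p = _softmax(np.einsum("nhid,nhjd->nhij", q, k, optimize=True) * scale)
        self._q, self._k, self._v, self._p, self._scale = q, k, v, p, scale
        self.last_attention = p
        out = np.einsum("nhij,nhjd->nhid", p, v, optimize=True)
        return self.wo(self._merge(out))

    def backward(self, g):
        d_out = self._split(self.wo.backward(g))
        p, q, k, v = self._p, self._q, self._k, self._v
        dp = np.einsum("nhid,nhjd->nhij", d_out, v, optimize=True)
        dv = np.einsum("nhij,nhid->nhjd", p, d_out, optimize=True)
        ds = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        dq = np.einsum("nhij,nhjd->nhid", ds, k, optimize=True) * self._scale
        dk = np.einsum("nhij,nhid->nhjd", ds, q, optimize=True) * self._scale
        gx = self.wq.backward(self._merge(dq))
        gx = gx + self.wk.backward(self._merge(dk))
        gx = gx + self.wv.backward(self._merge(dv))
        return gx


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: MHSA -> add & norm -> FFN -> add & norm."""

    def __init__(self, d_model, n_heads, ff_dim, dropout, rng):
        super().__init__()
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.drop1 = Dropout(dropout, rng)
        self.norm1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_dim, rng)
        self.act = ReLU()
        self.ff2 = Linear(ff_dim, d_model, rng)
        self.drop2 = Dropout(dropout, rng)
        self.norm2 = LayerNorm(d_model)

    def forward(self, x):
        h1 = self.norm1(x + self.drop1(self.attn(x)))
        ff = self.ff2(self.act(self.ff1(h1)))
        return self.norm2(h1 + self.drop2(ff))

    def backward(self, g):
        g1 = self.norm2.backward(g)
        gff = self.ff1.backward(self.act.backward(self.ff2.backward(
            self.drop2.backward(g1))))
        gh1 = self.norm1.backward(g1 + gff)
        gattn = self.attn.backward(self.drop1.backward(gh1))
        return gh1 + gattn
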