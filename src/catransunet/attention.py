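"""Dual Transformer-attention (DTA) bottleneck and its ablation substitutes.

Two complementary attention paths act on the deepest encoder features
``F_en`` (c x h x w, n = h*w positions):

* **TSA** (Transformer self-attention): 1x1-conv projections produce Q, K, V;
  the position-by-position map ``softmax(Q K^T / sqrt(d_k))`` re-weights V.
* **GSA** (global spatial attention): a channel-reduced projection
  (c' = c / reduction, reduction = 8 by default) yields two reshaped maps
  whose product, row-softmaxed, forms an n x n position-attention map that
  aggregates a full-width value branch.

The fused output is ``F = g1 * TSA(F_en) + g2 * GSA(F_en) + F_en`` with both
scalar gates *learned and initialized to zero*, so the bottleneck starts as
an exact identity and attention is blended in during training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import as_tensor
from .nn import BatchNorm2d, Conv2d, Module, Parameter


# ---------------------------------------------------------------------------
# Functional forms (operate on plain arrays; used by the modules and tests)
# ---------------------------------------------------------------------------

@dataclass
class QKVProjection:
    """Query/key/value matrices of shape (c, n) with their normalizer dim."""

    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    dk: int


def project_qkv(fen: np.ndarray, wq: np.ndarray, wk: np.ndarray,
                wv: np.ndarray) -> QKVProjection:
    """Flatten a (c, h, w) map and apply the three linear projections."""
    c = fen.shape[0]
    if wq.shape[1] != c or wk.shape[1] != c or wv.shape[1] != c:
        raise ValueError(f"projection weights expect {c} input channels")
    flat = fen.reshape(c, -1)
    return QKVProjection(Q=wq @ flat, K=wk @ flat, V=wv @ flat, dk=wq.shape[0])


def gsa_position_map(map1: np.ndarray, map2: np.ndarray) -> np.ndarray:
    """Row-stochastic n x n position-attention map from (n, c') and (c', n)."""
    logits = map1 @ map2
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class TSA(Module):
    """Transformer self-attention over spatial positions."""

    def __init__(self, channels: int, heads: int = 1, attn_scale: str = "sqrt",
                 rng: "np.random.Generator | None" = None):
        super().__init__()
        if channels % heads:
            raise ValueError("heads must divide the channel count")
        self.channels, self.heads = channels, heads
        self.attn_scale = attn_scale
        self.q = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.k = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.v = Conv2d(channels, channels, 1, bias=False, rng=rng)

    def _scale(self) -> float:
        dk = self.channels // self.heads
        return 1.0 / math.sqrt(dk) if self.attn_scale == "sqrt" else 1.0 / dk

    def _qkv(self, x):
        B, C, H, W = x.shape
        n, ch = H * W, C // self.heads
        q = ad.transpose(ad.reshape(self.q(x), (B, self.heads, ch, n)), (0, 1, 3, 2))
        k = ad.reshape(self.k(x), (B, self.heads, ch, n))
        v = ad.transpose(ad.reshape(self.v(x), (B, self.heads, ch, n)), (0, 1, 3, 2))
        return q, k, v  # q,v: (B,h,n,ch); k: (B,h,ch,n)

    def forward(self, x):
        x = as_tensor(x)
        B, C, H, W = x.shape
        q, k, v = self._qkv(x)
        attn = ad.softmax(ad.mul(ad.matmul(q, k), self._scale()), axis=-1)
        out = ad.matmul(attn, v)                     # (B,h,n,ch)
        out = ad.transpose(out, (0, 1, 3, 2))        # (B,h,ch,n)
        return ad.reshape(out, (B, C, H, W))

    def attention_map(self, x) -> np.ndarray:
        """The row-stochastic (B, heads, n, n) map, for inspection."""
        with ad.no_grad():
            q, k, _ = self._qkv(as_tensor(x))
            return ad.softmax(ad.mul(ad.matmul(q, k), self._scale()), axis=-1).data


class GSA(Module):
    """Global spatial (position) attention with channel reduction c' = c/8."""

    def __init__(self, channels: int, reduction: int = 8,
                 rng: "np.random.Generator | None" = None):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"gsa reduction {reduction} must divide channels {channels}")
        self.channels = channels
        self.reduced = channels // reduction
        self.reduce = Conv2d(channels, self.reduced, 1, bias=False, rng=rng)
        self.value = Conv2d(channels, channels, 1, bias=False, rng=rng)

    def _position_map(self, x):
        B, C, H, W = x.shape
        n = H * W
        fr = ad.reshape(self.reduce(x), (B, self.reduced, n))
        map1 = ad.transpose(fr, (0, 2, 1))           # (B, n, c')
        return ad.softmax(ad.matmul(map1, fr), axis=-1)   # (B, n, n)

    def forward(self, x):
        x = as_tensor(x)
        B, C, H, W = x.shape
        mpos = self._position_map(x)
        val = ad.transpose(ad.reshape(self.value(x), (B, C, H * W)), (0, 2, 1))
        out = ad.matmul(mpos, val)                   # (B, n, C)
        return ad.reshape(ad.transpose(out, (0, 2, 1)), (B, C, H, W))

    def attention_map(self, x) -> np.ndarray:
        with ad.no_grad():
            return self._position_map(as_tensor(x)).data


class DTA(Module):
    """Gated fusion g1*TSA + g2*GSA + input; gates start at exactly zero."""

    def __init__(self, channels: int, heads: int = 1, reduction: int = 8,
                 attn_scale: str = "sqrt",
                 rng: "np.random.Generator | None" = None):
        super().__init__()
        self.tsa = TSA(channels, heads, attn_scale, rng=rng)
        self.gsa = GSA(channels, reduction, rng=rng)
        self.gamma1 = Parameter(np.zeros(1))
        self.gamma2 = Parameter(np.zeros(1))

    def forward(self, x):
        x = as_tensor(x)
        return ad.add(ad.add(ad.mul(self.tsa(x), self.gamma1),
                             ad.mul(self.gsa(x), self.gamma2)), x)


class GatedAttention(Module):
    """Single-path ablation bottleneck: x + gamma * attention(x)."""

    def __init__(self, attention: Module):
        super().__init__()
        self.attention = attention
        self.gamma = Parameter(np.zeros(1))

    def forward(self, x):
        x = as_tensor(x)
        return ad.add(ad.mul(self.attention(x), self.gamma), x)


class ASPP(Module):
    """Atrous spatial pyramid pooling substitute for the bottleneck.

    Four parallel dilated 3x3 branches (same rates as the encoder blocks)
    concatenated and fused by a 1x1 convolution back to the input width.
    """

    def __init__(self, channels: int, rates=(1, 3, 5, 7),
                 rng: "np.random.Generator | None" = None):
        super().__init__()
        if channels % len(rates):
            raise ValueError("channels must be divisible by the branch count")
        branch = channels // len(rates)
        self.rates = tuple(rates)
        for i, r in enumerate(self.rates):
            setattr(self, f"branch{i}_conv",
                    Conv2d(channels, branch, 3, padding=r, dilation=r,
                           bias=False, rng=rng))
            setattr(self, f"branch{i}_bn", BatchNorm2d(branch))
        self.fuse_conv = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.fuse_bn = BatchNorm2d(channels)

    def forward(self, x):
        branches = [
            getattr(self, f"branch{i}_bn")(getattr(self, f"branch{i}_conv")(x))
            for i in range(len(self.rates))
        ]
        return ad.relu(self.fuse_bn(self.fuse_conv(ad.concat(branches, axis=1))))


def make_bottleneck(variant: str, channels: int, heads: int, reduction: int,
                    attn_scale: str, rates,
                    rng: "np.random.Generator | None" = None) -> Module:
    from .nn import Identity

    if variant == "DTA":
        return DTA(channels, heads, reduction, attn_scale, rng=rng)
    if variant == "TSA_only":
        return GatedAttention(TSA(channels, heads, attn_scale, rng=rng))
    if variant == "GSA_only":
        return GatedAttention(GSA(channels, reduction, rng=rng))
    if variant == "ASPP":
        return ASPP(channels, rates, rng=rng)
    if variant == "none":
        return Identity()
    raise ValueError(f"unknown bottleneck variant {variant!r}")
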