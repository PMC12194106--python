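"""Cross-attention skip connections (CASC) between encoder and decoder.

A skip fuses the *low-level* encoder map at a stage's resolution with the
*high-level* decoder map up-sampled to the same resolution. Both inputs are
first channel-gated (spatial mean -> linear -> sigmoid, Eq. of the channel
selection), then the low map provides K and V and the high map provides Q
for a scaled dot-product cross-attention over positions; the attended low
map is concatenated with the high map and projected back to the stage
width.

Full-resolution position attention is quadratic in pixel count, so the
attention operates on an average-pooled grid of at most ``grid`` (default
32) pixels per side, and the attended map is up-sampled back before
concatenation.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import as_tensor
from .nn import BatchNorm2d, Conv2d, Linear, Module


def channel_select(f: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gate a (c, h, w) map by sigmoid(W @ spatial-mean), per channel."""
    c = f.shape[0]
    pooled = f.reshape(c, -1).mean(axis=1)
    gate = 1.0 / (1.0 + np.exp(-(w @ pooled)))
    return gate[:, None, None] * f


class ChannelSelect(Module):
    """Per-channel sigmoid gating from the pooled channel descriptor."""

    def __init__(self, channels: int, rng: "np.random.Generator | None" = None):
        super().__init__()
        self.gate = Linear(channels, channels, bias=False, rng=rng)

    def forward(self, x):
        x = as_tensor(x)
        B, C = x.shape[0], x.shape[1]
        pooled = ad.mean(x, axis=(2, 3))                # (B, C)
        aw = ad.sigmoid(self.gate(pooled))
        return ad.mul(x, ad.reshape(aw, (B, C, 1, 1)))


class CASCBlock(Module):
    """Cross-attention fusion of one encoder skip with the decoder stream."""

    def __init__(self, channels: int, grid: int = 32, attn_scale: str = "sqrt",
                 rng: "np.random.Generator | None" = None):
        super().__init__()
        self.channels, self.grid = channels, grid
        self.attn_scale = attn_scale
        self.select_low = ChannelSelect(channels, rng=rng)
        self.select_high = ChannelSelect(channels, rng=rng)
        self.q = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.k = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.v = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.fuse_conv = Conv2d(2 * channels, channels, 1, bias=False, rng=rng)
        self.fuse_bn = BatchNorm2d(channels)

    def _scale(self) -> float:
        return (1.0 / math.sqrt(self.channels) if self.attn_scale == "sqrt"
                else 1.0 / self.channels)

    def _attended(self, lowg, highg):
        B, C, H, W = lowg.shape
        f = max(1, H // self.grid)
        lp = ad.avgpool(lowg, f) if f > 1 else lowg
        hp = ad.avgpool(highg, f) if f > 1 else highg
        h2, w2 = lp.shape[2], lp.shape[3]
        n = h2 * w2
        q = ad.transpose(ad.reshape(self.q(hp), (B, C, n)), (0, 2, 1))  # (B,n,C)
        k = ad.reshape(self.k(lp), (B, C, n))                           # (B,C,n)
        v = ad.transpose(ad.reshape(self.v(lp), (B, C, n)), (0, 2, 1))  # (B,n,C)
        attn = ad.softmax(ad.mul(ad.matmul(q, k), self._scale()), axis=-1)
        att = ad.matmul(attn, v)                                        # (B,n,C)
        att = ad.reshape(ad.transpose(att, (0, 2, 1)), (B, C, h2, w2))
        if f > 1:
            att = ad.upsample_nearest(att, f)
        return att, attn

    def forward(self, low, high):
        low, high = as_tensor(low), as_tensor(high)
        if low.shape != high.shape:
            raise ValueError(
                f"CASC resolution/width mismatch: {low.shape} vs {high.shape}")
        lowg = self.select_low(low)
        highg = self.select_high(high)
        att, _ = self._attended(lowg, highg)
        return ad.relu(self.fuse_bn(self.fuse_conv(ad.concat([att, highg], axis=1))))

    def attention_map(self, low, high) -> np.ndarray:
        """Row-stochastic cross-attention map on the pooled grid."""
        with ad.no_grad():
            lowg = self.select_low(as_tensor(low))
            highg = self.select_high(as_tensor(high))
            _, attn = self._attended(lowg, highg)
            return attn.data


class PlainSkip(Module):
    """Classic U-Net skip: concatenate and project to the stage width."""

    def __init__(self, channels: int, rng: "np.random.Generator | None" = None):
        super().__init__()
        self.fuse_conv = Conv2d(2 * channels, channels, 1, bias=False, rng=rng)
        self.fuse_bn = BatchNorm2d(channels)

    def forward(self, low, high):
        low, high = as_tensor(low), as_tensor(high)
        if low.shape != high.shape:
            raise ValueError(
                f"skip resolution/width mismatch: {low.shape} vs {high.shape}")
        return ad.relu(self.fuse_bn(self.fuse_conv(ad.concat([low, high], axis=1))))


class NoSkip(Module):
    """Decoder-only path: the encoder map is ignored."""

    def forward(self, low, high):
        return as_tensor(high)


def make_skip(variant: str, channels: int, grid: int, attn_scale: str,
              rng: "np.random.Generator | None" = None) -> Module:
    if variant == "CASC":
        return CASCBlock(channels, grid, attn_scale, rng=rng)
    if variant == "plain_skip":
        return PlainSkip(channels, rng=rng)
    if variant == "none":
        return NoSkip()
    raise ValueError(f"unknown skip variant {variant!r}")
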