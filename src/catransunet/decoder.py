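"""Residual deconvolution decoder stages and the sigmoid prediction head.

Each decoder block applies two 3x3 convolutions (Conv -> BN -> ReLU order)
with a residual shortcut across the pair (1x1-projected when the widths
differ), then doubles the spatial size — by a 2x2 stride-2 transposed
convolution by default, or nearest-neighbour up-sampling + 1x1 convolution.
The head is a 1x1 convolution followed by a sigmoid, producing a per-pixel
pest probability in (0, 1).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import as_tensor
from .nn import BatchNorm2d, Conv2d, ConvTranspose2x2, Identity, Module


class DecoderBlock(Module):
    def __init__(self, in_channels: int, out_channels: int,
                 upsample: str = "deconv",
                 rng: "np.random.Generator | None" = None):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.conv1 = Conv2d(in_channels, out_channels, 3, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        if in_channels != out_channels:
            self.res_conv = Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)
            self.res_bn = BatchNorm2d(out_channels)
        else:
            self.res_conv = Identity()
            self.res_bn = Identity()
        if upsample == "deconv":
            self.up = ConvTranspose2x2(out_channels, out_channels, rng=rng)
            self._up_mode = "deconv"
        elif upsample == "nearest":
            self.up = Conv2d(out_channels, out_channels, 1, rng=rng)
            self._up_mode = "nearest"
        else:
            raise ValueError(f"unknown upsample mode {upsample!r}")

    def forward(self, x):
        x = as_tensor(x)
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"decoder block expects {self.in_channels} channels, got {x.shape[1]}")
        h = ad.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        h = ad.relu(h + self.res_bn(self.res_conv(x)))
        if self._up_mode == "deconv":
            return self.up(h)
        return self.up(ad.upsample_nearest(h, 2))


class PredictionHead(Module):
    """1x1 convolution + sigmoid -> single-channel probability map."""

    def __init__(self, in_channels: int, rng: "np.random.Generator | None" = None):
        super().__init__()
        self.conv = Conv2d(in_channels, 1, 1, bias=True, rng=rng)

    def forward(self, x):
        return ad.sigmoid(self.conv(x))
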