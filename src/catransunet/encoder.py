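"""Four-stage encoder built from residual dilated Inception (RDI) blocks.

Each RDI block runs four parallel 3x3 convolutions with dilation rates
1/3/5/7 (effective kernel extents 3/7/11/15), concatenates the branches,
fuses them with a 1x1 convolution + batch norm, adds a 1x1-projected
residual of the block input, and applies ReLU. Ablation variants drop the
dilation (plain Inception), the residual, or the whole multi-branch design.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .config import ModelConfig
from .nn import BatchNorm2d, Conv2d, Module


def effective_extent(kernel: int, dilation: int) -> int:
    """Spatial extent of a dilated kernel: k + (k-1)(r-1)."""
    return kernel + (kernel - 1) * (dilation - 1)


class DRIBlock(Module):
    """Residual dilated Inception block (rates configurable, residual optional)."""

    def __init__(self, in_channels: int, out_channels: int,
                 dilation_rates=(1, 3, 5, 7), residual: bool = True,
                 rng: "np.random.Generator | None" = None):
        super().__init__()
        if out_channels % len(dilation_rates):
            raise ValueError("out_channels must be divisible by the branch count")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.dilation_rates = tuple(dilation_rates)
        self.residual = residual
        branch = out_channels // len(dilation_rates)
        self.branch_channels = branch
        for i, r in enumerate(self.dilation_rates):
            # "same" padding equals the dilation rate for a 3x3 kernel
            setattr(self, f"branch{i}_conv",
                    Conv2d(in_channels, branch, 3, padding=r, dilation=r,
                           bias=False, rng=rng))
            setattr(self, f"branch{i}_bn", BatchNorm2d(branch))
        self.fuse_conv = Conv2d(out_channels, out_channels, 1, bias=False, rng=rng)
        self.fuse_bn = BatchNorm2d(out_channels)
        if residual:
            self.res_conv = Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)
            self.res_bn = BatchNorm2d(out_channels)

    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"DRIBlock expects {self.in_channels} channels, got {x.shape[1]}")
        branches = [
            getattr(self, f"branch{i}_bn")(getattr(self, f"branch{i}_conv")(x))
            for i in range(len(self.dilation_rates))
        ]
        fused = self.fuse_bn(self.fuse_conv(ad.concat(branches, axis=1)))
        if self.residual:
            fused = fused + self.res_bn(self.res_conv(x))
        return ad.relu(fused)


class PlainConvBlock(Module):
    """Two 3x3 conv + BN + ReLU, the classic U-Net encoder stage."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: "np.random.Generator | None" = None):
        super().__init__()
        self.in_channels = in_channels
        self.conv1 = Conv2d(in_channels, out_channels, 3, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)

    def forward(self, x):
        h = ad.relu(self.bn1(self.conv1(x)))
        return ad.relu(self.bn2(self.conv2(h)))


def _make_stage(variant: str, cin: int, cout: int, rates, rng):
    if variant == "RDI":
        return DRIBlock(cin, cout, rates, residual=True, rng=rng)
    if variant == "dilated_inception":
        return DRIBlock(cin, cout, rates, residual=False, rng=rng)
    if variant == "inception":
        return DRIBlock(cin, cout, (1, 1, 1, 1), residual=False, rng=rng)
    if variant == "plain_conv":
        return PlainConvBlock(cin, cout, rng=rng)
    raise ValueError(f"unknown encoder variant {variant!r}")


class Encoder(Module):
    """Four encoder stages, each followed by 2x2 max-pooling."""

    def __init__(self, cfg: ModelConfig, rng: "np.random.Generator | None" = None):
        super().__init__()
        widths = [cfg.in_channels] + list(cfg.stage_widths)
        for i in range(4):
            setattr(self, f"stage{i + 1}",
                    _make_stage(cfg.encoder_variant, widths[i], widths[i + 1],
                                tuple(cfg.dilation_rates), rng))

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(f"encoder input must be divisible by 16, got {h}x{w}")
        skips = []
        for i in range(4):
            x = getattr(self, f"stage{i + 1}")(x)
            skips.append(x)
            x = ad.maxpool2x2(x)
        return skips, x
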