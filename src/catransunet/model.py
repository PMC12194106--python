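"""Assembly of the full cross-attention TransU-Net and its ablation variants.

The network is an encoder–decoder with four 2x-downsampling stages:

    image -> [RDI stage + maxpool] x4 -> bottleneck (DTA) ->
    [decoder stage -> CASC fusion with the matching encoder skip] x4 ->
    1x1 conv + sigmoid -> per-pixel pest probability

Only the deepest (pooled stage-4) feature map feeds the bottleneck; the four
pre-pooling stage outputs feed the skip connections. Ablation variants swap
the encoder block family, the bottleneck, or the skip type without changing
this outer topology, mirroring the published ablation grid.

Also provides capacity accounting: exact trainable-parameter enumeration
and forward-pass FLOP estimation (multiply-accumulate counted as 2 FLOPs,
covering convolutions, normalizations, activations and attention products).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product

import numpy as np

from .attention import make_bottleneck
from .autodiff import FlopCounter, as_tensor, count_flops, no_grad
from .config import (BOTTLENECK_VARIANTS, ENCODER_VARIANTS, SKIP_VARIANTS,
                     ModelConfig)
from .decoder import DecoderBlock, PredictionHead
from .encoder import Encoder
from .nn import BatchNorm2d, Conv2d, Identity, Module, ReLU, Sequential
from .skip import make_skip


class CATransUNet(Module):
    """The full segmentation model; built from a :class:`ModelConfig`."""

    def __init__(self, cfg: ModelConfig, rng: "np.random.Generator | None" = None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        s1, s2, s3, s4 = cfg.stage_widths
        wb = cfg.bottleneck_width
        self.encoder = Encoder(cfg, rng=rng)
        if wb != s4:
            self.bottleneck_entry = Sequential(
                Conv2d(s4, wb, 1, bias=False, rng=rng), BatchNorm2d(wb), ReLU())
        else:
            self.bottleneck_entry = Identity()
        self.bottleneck = make_bottleneck(
            cfg.bottleneck_variant, wb, cfg.attention_heads, cfg.gsa_reduction,
            cfg.attn_scale, tuple(cfg.dilation_rates), rng=rng)
        self.decoder4 = DecoderBlock(wb, s4, cfg.upsample, rng=rng)
        self.decoder3 = DecoderBlock(s4, s3, cfg.upsample, rng=rng)
        self.decoder2 = DecoderBlock(s3, s2, cfg.upsample, rng=rng)
        self.decoder1 = DecoderBlock(s2, s1, cfg.upsample, rng=rng)
        for i, w in zip((4, 3, 2, 1), (s4, s3, s2, s1)):
            setattr(self, f"skip{i}",
                    make_skip(cfg.skip_variant, w, cfg.casc_grid, cfg.attn_scale,
                              rng=rng))
        self.head = PredictionHead(s1, rng=rng)

    def _features(self, x):
        x = as_tensor(x)
        if x.ndim != 4:
            raise ValueError(f"expected a (B,C,H,W) batch, got shape {x.shape}")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} input, "
                f"got {x.shape[2]}x{x.shape[3]} (the model never resizes silently)")
        skips, deep = self.encoder(x)
        h = self.bottleneck(self.bottleneck_entry(deep))
        for i in (4, 3, 2, 1):
            h = getattr(self, f"decoder{i}")(h)
            h = getattr(self, f"skip{i}")(skips[i - 1], h)
        return h

    def forward(self, x):
        """Per-pixel pest probability map, values in (0, 1)."""
        return self.head(self._features(x))

    def forward_logits(self, x):
        """Pre-sigmoid scores (the training loss operates on these)."""
        return self.head.conv(self._features(x))


def build_model(cfg: ModelConfig,
                rng: "np.random.Generator | None" = None) -> CATransUNet:
    """Construct the network (or any ablation variant) from a config."""
    return CATransUNet(cfg, rng=rng)


# ---------------------------------------------------------------------------
# Capacity accounting
# ---------------------------------------------------------------------------

@dataclass
class ParamReport:
    """Trainable-parameter totals with a per-block breakdown."""

    total_params: int
    per_block_params: dict
    gflops: "float | None" = None
    input_size: "int | None" = None

    def to_json(self) -> str:
        return json.dumps({
            "total_params": self.total_params,
            "per_block_params": self.per_block_params,
            "gflops": self.gflops,
            "input_size": self.input_size,
        }, indent=2)

    def pretty(self) -> str:
        lines = [f"{'block':<20} {'params':>12}"]
        for name, n in sorted(self.per_block_params.items()):
            lines.append(f"{name:<20} {n:>12,}")
        lines.append(f"{'TOTAL':<20} {self.total_params:>12,}")
        if self.gflops is not None:
            lines.append(f"forward GFLOPs @ {self.input_size}: {self.gflops:.1f}")
        return "\n".join(lines)


def count_parameters(model: Module) -> ParamReport:
    """Enumerate every trainable parameter, grouped by top-level block."""
    per_block: dict = {}
    total = 0
    for name, p in model.named_parameters():
        block = name.split(".", 1)[0]
        per_block[block] = per_block.get(block, 0) + p.size
        total += p.size
    return ParamReport(total_params=int(total),
                       per_block_params={k: int(v) for k, v in per_block.items()})


def estimate_flops(model: CATransUNet, input_size: "int | None" = None) -> float:
    """Forward-pass GFLOPs measured by an instrumented evaluation pass.

    Every primitive reports its cost as it executes (MAC x 2 for
    convolutions and attention matrix products; per-element counts for
    normalizations, activations and pooling), so the figure reflects the
    exact composition of the built model at the given input size.
    """
    size = input_size or model.cfg.input_size
    if size != model.cfg.input_size:
        model = build_model(model.cfg.replace(input_size=size))
    was_training = model.training
    model.eval()
    counter = FlopCounter()
    x = np.zeros((1, model.cfg.in_channels, size, size), dtype=np.float32)
    with no_grad(), count_flops(counter):
        model(x)
    if was_training:
        model.train()
    return counter.total / 1e9


def model_report(model: CATransUNet, input_size: "int | None" = None) -> ParamReport:
    """Parameter counts plus forward GFLOPs in one report."""
    report = count_parameters(model)
    report.input_size = input_size or model.cfg.input_size
    report.gflops = estimate_flops(model, report.input_size)
    return report


# ---------------------------------------------------------------------------
# Ablation variant registry
# ---------------------------------------------------------------------------

# Published ablation rows: (name, encoder, bottleneck, skip). "--" cells mean
# the plain U-Net component (plain conv stages / no bottleneck / plain skip).
TABLE3_ROWS = (
    ("baseline_unet", "plain_conv", "none", "plain_skip"),
    ("rdi_casc", "RDI", "none", "CASC"),
    ("inception_aspp", "inception", "ASPP", "plain_skip"),
    ("aspp_casc", "plain_conv", "ASPP", "CASC"),
    ("rdi_dta", "RDI", "DTA", "plain_skip"),
    ("dta_casc", "plain_conv", "DTA", "CASC"),
    ("rdi_aspp_casc", "RDI", "ASPP", "CASC"),
    ("rdi_gsa_casc", "RDI", "GSA_only", "CASC"),
    ("rdi_tsa_casc", "RDI", "TSA_only", "CASC"),
    ("dilated_inception_dta_casc", "dilated_inception", "DTA", "CASC"),
    ("full_model", "RDI", "DTA", "CASC"),
)


def table3_variants(base: "ModelConfig | None" = None):
    """(name, config) pairs for the published ablation rows."""
    base = base or ModelConfig()
    return [(name, base.replace(encoder_variant=e, bottleneck_variant=b,
                                skip_variant=s))
            for name, e, b, s in TABLE3_ROWS]


def variant_grid(base: "ModelConfig | None" = None):
    """Every encoder x bottleneck x skip combination (the full ablation grid)."""
    base = base or ModelConfig()
    out = []
    for e, b, s in product(ENCODER_VARIANTS, BOTTLENECK_VARIANTS, SKIP_VARIANTS):
        name = f"{e}+{b}+{s}"
        out.append((name, base.replace(encoder_variant=e, bottleneck_variant=b,
                                       skip_variant=s)))
    return out
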