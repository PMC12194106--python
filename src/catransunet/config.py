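"""Configuration objects: architecture, training protocol, synthetic scenes.

``ModelConfig`` describes the full network (stage widths, dilation rates,
component variant selectors) and round-trips through YAML; the shipped
``default_config.yaml`` holds the calibrated default architecture.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

ENCODER_VARIANTS = ("RDI", "inception", "dilated_inception", "plain_conv")
BOTTLENECK_VARIANTS = ("DTA", "ASPP", "TSA_only", "GSA_only", "none")
SKIP_VARIANTS = ("CASC", "plain_skip", "none")


class ConfigurationError(ValueError):
    """Raised for invalid architecture or training configurations."""


# Stage widths calibrated once against the published capacity figures
# (14.6 M parameters / 18.9 GFLOPs at 256x256); see docs/methods.md.
_DEFAULT_STAGE_WIDTHS = [16, 48, 120, 576]
_DEFAULT_BOTTLENECK_WIDTH = 640


@dataclass
class ModelConfig:
    """Full architecture description of the segmentation network."""

    in_channels: int = 3
    stage_widths: list = field(default_factory=lambda: list(_DEFAULT_STAGE_WIDTHS))
    bottleneck_width: int = _DEFAULT_BOTTLENECK_WIDTH
    dilation_rates: list = field(default_factory=lambda: [1, 3, 5, 7])
    attention_heads: int = 1
    gsa_reduction: int = 8
    encoder_variant: str = "RDI"
    bottleneck_variant: str = "DTA"
    skip_variant: str = "CASC"
    input_size: int = 256
    attn_scale: str = "sqrt"     # "sqrt" => /sqrt(dk); "linear" => literal /dk
    casc_grid: int = 32          # max K/Q/V grid side for the cross-attention skips
    upsample: str = "deconv"     # "deconv" (2x2 transposed conv) or "nearest"+1x1

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.encoder_variant not in ENCODER_VARIANTS:
            raise ConfigurationError(f"unknown encoder_variant {self.encoder_variant!r}")
        if self.bottleneck_variant not in BOTTLENECK_VARIANTS:
            raise ConfigurationError(
                f"unknown bottleneck_variant {self.bottleneck_variant!r}")
        if self.skip_variant not in SKIP_VARIANTS:
            raise ConfigurationError(f"unknown skip_variant {self.skip_variant!r}")
        if self.upsample not in ("deconv", "nearest"):
            raise ConfigurationError(f"unknown upsample mode {self.upsample!r}")
        if self.attn_scale not in ("sqrt", "linear"):
            raise ConfigurationError(f"unknown attn_scale {self.attn_scale!r}")
        if len(self.stage_widths) != 4 or any(w <= 0 for w in self.stage_widths):
            raise ConfigurationError("stage_widths must be 4 positive integers")
        uses_dilation = self.encoder_variant in ("RDI", "dilated_inception")
        if uses_dilation and len(self.dilation_rates) != 4:
            raise ConfigurationError("dilation_rates must have exactly 4 entries")
        if any(r < 1 for r in self.dilation_rates):
            raise ConfigurationError("dilation rates must be positive")
        if self.bottleneck_width <= 0:
            raise ConfigurationError("bottleneck_width must be positive")
        if self.bottleneck_variant in ("DTA", "GSA_only") and \
                self.bottleneck_width % self.gsa_reduction != 0:
            raise ConfigurationError(
                f"gsa_reduction={self.gsa_reduction} must divide "
                f"bottleneck_width={self.bottleneck_width}")
        if self.bottleneck_width % self.attention_heads != 0:
            raise ConfigurationError("attention_heads must divide bottleneck_width")
        if self.input_size % 16 != 0:
            raise ConfigurationError(
                "input_size must be divisible by 16 (four 2x downsamplings)")
        for w in self.stage_widths:
            if w % 4 != 0:
                raise ConfigurationError(
                    "stage widths must be divisible by 4 (four parallel branches)")

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def replace(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


@dataclass
class TrainConfig:
    """Optimization protocol: Adam with plateau-based learning-rate decay."""

    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    total_iterations: int = 3000
    plateau_factor: float = 0.1
    plateau_patience: int = 4       # validation evaluations without improvement
    val_interval: int = 50          # iterations between validation evaluations
    val_fraction: float = 0.1
    seed: int = 0
    pos_weight: "float | None" = None   # None = unweighted; "balanced" via trainer

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ConfigurationError("rates must be positive")
        if not 0 < self.plateau_factor < 1:
            raise ConfigurationError("plateau_factor must lie in (0,1)")
        if self.batch_size < 1 or self.total_iterations < 1:
            raise ConfigurationError("batch_size/total_iterations must be >= 1")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SceneParams:
    """Parameters of the procedural field-scene generator.

    Defaults emulate the field conditions the model targets: a handful of
    pests per frame spanning tiny to large scales, elongated bodies with
    thin appendages, cluttered vegetation backgrounds, and (optionally)
    pests whose luminance nearly matches the background.
    """

    canvas_size: int = 640
    n_pests: tuple = (1, 5)
    pest_scale_range: tuple = (0.01, 0.25)
    body_aspect_range: tuple = (1.5, 4.0)
    n_appendages: tuple = (2, 8)
    contrast_level: str = "normal"      # "normal" or "low" (+-10% luminance)
    background_style: str = "leaf_stripes"  # leaf_stripes | soil_texture | clutter
    occlusion_prob: float = 0.2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.pest_scale_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("pest_scale_range must lie within (0,1)")
        if self.contrast_level not in ("normal", "low"):
            raise ConfigurationError(f"unknown contrast_level {self.contrast_level!r}")
        if self.background_style not in ("leaf_stripes", "soil_texture", "clutter"):
            raise ConfigurationError(
                f"unknown background_style {self.background_style!r}")
        if self.n_pests[0] > self.n_pests[1] or self.n_pests[0] < 0:
            raise ConfigurationError("n_pests range is degenerate")

    def replace(self, **kwargs) -> "SceneParams":
        return replace(self, **kwargs)


def default_config_path() -> Path:
    return Path(__file__).with_name("default_config.yaml")
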