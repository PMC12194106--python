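in_channels: 3
stage_widths:
- 16
- 48
- 120
- 576
bottleneck_width: 640
dilation_rates:
- 1
- 3
- 5
- 7
attention_heads: 1
gsa_reduction: 8
encoder_variant: RDI
bottleneck_variant: DTA
skip_variant: CASC
input_size: 256
attn_scale: sqrt
casc_grid: 32
upsample: deconv
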