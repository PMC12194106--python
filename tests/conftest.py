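import numpy as np
import pytest

from catransunet import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    """A slim configuration for fast structural tests."""
    return ModelConfig(stage_widths=[8, 16, 24, 32], bottleneck_width=32,
                       input_size=64, casc_grid=16)


def numeric_gradient(fn, x, eps=1e-6):
    """Central finite differences of a scalar-valued fn at x (float64)."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat, gflat = x.ravel(), g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        f1 = fn(x)
        flat[i] = orig - eps
        f2 = fn(x)
        flat[i] = orig
        gflat[i] = (f1 - f2) / (2 * eps)
    return g
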