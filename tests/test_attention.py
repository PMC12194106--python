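"""Bottleneck attention: oracle equivalence, stochasticity, identity gates."""

import math

import numpy as np
import pytest

from catransunet import DTA, GSA, TSA, gsa_position_map, project_qkv
from catransunet.attention import ASPP, GatedAttention


# ---------------------------------------------------------------------------
# Brute-force references (triple nested loops, independent of the vector path)
# ---------------------------------------------------------------------------

def ref_softmax_rows(logits):
    out = np.zeros_like(logits)
    for i in range(logits.shape[0]):
        e = np.exp(logits[i] - logits[i].max())
        out[i] = e / e.sum()
    return out


def ref_tsa(x, wq, wk, wv, scale):
    """x: (c,h,w); weights (c,c); returns (c,h,w)."""
    c, h, w = x.shape
    n = h * w
    flat = x.reshape(c, n)
    Q, K, V = wq @ flat, wk @ flat, wv @ flat
    logits = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for cc in range(c):
                logits[i, j] += Q[cc, i] * K[cc, j]
    A = ref_softmax_rows(logits * scale)
    out = np.zeros((c, n))
    for cc in range(c):
        for i in range(n):
            for j in range(n):
                out[cc, i] += A[i, j] * V[cc, j]
    return out.reshape(c, h, w)


def ref_gsa(x, w_reduce, w_value):
    c, h, w = x.shape
    n = h * w
    flat = x.reshape(c, n)
    fr = w_reduce @ flat          # (c', n)
    val = w_value @ flat          # (c, n)
    cp = fr.shape[0]
    logits = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for k in range(cp):
                logits[i, j] += fr[k, i] * fr[k, j]
    M = ref_softmax_rows(logits)
    out = np.zeros((c, n))
    for cc in range(c):
        for i in range(n):
            for j in range(n):
                out[cc, i] += M[i, j] * val[cc, j]
    return out.reshape(c, h, w)


# ---------------------------------------------------------------------------
# QKV projection
# ---------------------------------------------------------------------------

def test_identity_projection_returns_flattened_input(rng):
    fen = rng.standard_normal((4, 2, 2))
    eye = np.eye(4)
    proj = project_qkv(fen, eye, eye, eye)
    assert np.allclose(proj.Q, fen.reshape(4, 4))


def test_zero_key_projection_gives_zero_logits(rng):
    fen = rng.standard_normal((4, 2, 2))
    proj = project_qkv(fen, np.eye(4), np.zeros((4, 4)), np.eye(4))
    assert np.all(proj.K == 0)
    assert np.all(proj.Q.T @ proj.K == 0)


def test_projection_matches_entrywise_oracle(rng):
    fen = rng.standard_normal((4, 2, 2))
    wq, wk, wv = (rng.standard_normal((4, 4)) for _ in range(3))
    proj = project_qkv(fen, wq, wk, wv)
    flat = fen.reshape(4, 4)
    for out, wm in ((proj.Q, wq), (proj.K, wk), (proj.V, wv)):
        expect = np.zeros((4, 4))
        for r in range(4):
            for col in range(4):
                for k in range(4):
                    expect[r, col] += wm[r, k] * flat[k, col]
        assert np.allclose(out, expect)


def test_projection_channel_mismatch_raises(rng):
    with pytest.raises(ValueError, match="channels"):
        project_qkv(rng.standard_normal((4, 2, 2)), np.eye(3), np.eye(4),
                    np.eye(4))


# ---------------------------------------------------------------------------
# TSA
# ---------------------------------------------------------------------------

def test_tsa_single_position_returns_value_branch(rng):
    tsa = TSA(4, rng=rng)
    x = rng.standard_normal((1, 4, 1, 1)).astype(np.float32)
    out = tsa(x)
    v = tsa.v(np.asarray(x, dtype=np.float32))
    assert np.allclose(out.data, v.data, atol=1e-6)


def test_tsa_constant_input_gives_constant_output(rng):
    tsa = TSA(4, rng=rng)
    x = np.ones((1, 4, 3, 3), dtype=np.float32) * \
        rng.standard_normal((1, 4, 1, 1)).astype(np.float32)
    out = tsa(x).data
    assert np.allclose(out, out[:, :, :1, :1], atol=1e-6)


@pytest.mark.parametrize("hw", [2, 3, 4])
def test_tsa_matches_bruteforce_oracle(rng, hw):
    tsa = TSA(2, rng=rng)
    x = rng.standard_normal((1, 2, hw, hw))
    out = tsa(x).data[0]
    expect = ref_tsa(x[0],
                     tsa.q.weight.data[:, :, 0, 0],
                     tsa.k.weight.data[:, :, 0, 0],
                     tsa.v.weight.data[:, :, 0, 0],
                     1.0 / math.sqrt(2))
    assert np.abs(out - expect).max() / (np.abs(expect).max() + 1e-12) < 1e-5


def test_tsa_rows_are_stochastic(rng):
    tsa = TSA(8, heads=2, rng=rng)
    x = rng.standard_normal((2, 8, 4, 4))
    attn = tsa.attention_map(x)
    assert attn.shape == (2, 2, 16, 16)
    assert np.allclose(attn.sum(-1), 1.0, atol=1e-6)
    assert np.all(attn >= 0)


def test_tsa_permutation_equivariance(rng):
    """Permuting spatial positions permutes the output identically."""
    tsa = TSA(4, rng=rng)
    x = rng.standard_normal((1, 4, 2, 2))
    perm = np.array([2, 0, 3, 1])
    xp = x.reshape(1, 4, 4)[:, :, perm].reshape(1, 4, 2, 2)
    out = tsa(x).data.reshape(1, 4, 4)
    outp = tsa(xp).data.reshape(1, 4, 4)
    assert np.allclose(outp, out[:, :, perm], atol=1e-5)


def test_linear_scale_switch_changes_normalizer(rng):
    x = rng.standard_normal((1, 4, 2, 2))
    t_sqrt = TSA(4, attn_scale="sqrt", rng=np.random.default_rng(0))
    t_lin = TSA(4, attn_scale="linear", rng=np.random.default_rng(0))
    assert t_sqrt._scale() == pytest.approx(0.5)
    assert t_lin._scale() == pytest.approx(0.25)
    assert not np.allclose(t_sqrt(x).data, t_lin(x).data)


# ---------------------------------------------------------------------------
# GSA
# ---------------------------------------------------------------------------

def test_position_map_uniform_for_zero_features():
    m = gsa_position_map(np.zeros((4, 2)), np.zeros((2, 4)))
    assert np.allclose(m, 0.25)


def test_position_map_single_position():
    m = gsa_position_map(np.ones((1, 3)), np.ones((3, 1)))
    assert np.allclose(m, [[1.0]])


def test_position_map_matches_hand_softmax(rng):
    map1 = rng.standard_normal((3, 2))
    map2 = rng.standard_normal((2, 3))
    assert np.allclose(gsa_position_map(map1, map2),
                       ref_softmax_rows(map1 @ map2), atol=1e-12)


def test_gsa_uniform_map_averages_value_branch(rng):
    gsa = GSA(8, reduction=8, rng=rng)
    gsa.reduce.weight.data[...] = 0.0  # zero logits -> uniform attention
    x = rng.standard_normal((1, 8, 2, 2)).astype(np.float32)
    out = gsa(x).data
    val = gsa.value(np.asarray(x, np.float32)).data
    assert np.allclose(out, val.mean(axis=(2, 3), keepdims=True), atol=1e-6)


def test_gsa_single_position_is_value_branch(rng):
    gsa = GSA(8, rng=rng)
    x = rng.standard_normal((1, 8, 1, 1)).astype(np.float32)
    assert np.allclose(gsa(x).data, gsa.value(np.asarray(x, np.float32)).data,
                       atol=1e-6)


@pytest.mark.parametrize("hw", [2, 4])
def test_gsa_matches_bruteforce_oracle(rng, hw):
    gsa = GSA(8, reduction=8, rng=rng)
    x = rng.standard_normal((1, 8, hw, hw))
    out = gsa(x).data[0]
    expect = ref_gsa(x[0], gsa.reduce.weight.data[:, :, 0, 0],
                     gsa.value.weight.data[:, :, 0, 0])
    assert np.abs(out - expect).max() / (np.abs(expect).max() + 1e-12) < 1e-5


def test_gsa_requires_divisible_channels(rng):
    with pytest.raises(ValueError, match="divide"):
        GSA(10, reduction=8, rng=rng)


# ---------------------------------------------------------------------------
# DTA fusion
# ---------------------------------------------------------------------------

def test_zero_gates_give_bitwise_identity(rng):
    dta = DTA(8, rng=rng)
    x = rng.standard_normal((2, 8, 3, 3)).astype(np.float32)
    out = dta(x).data
    assert out.tobytes() == x.tobytes()


def test_gate_one_selects_tsa_branch(rng):
    dta = DTA(8, rng=rng)
    dta.gamma1.data[...] = 1.0
    x = np.zeros((1, 8, 2, 2), dtype=np.float32)
    assert np.allclose(dta(x).data, dta.tsa(x).data)


def test_half_gates_match_compositional_oracle(rng):
    dta = DTA(8, rng=rng)
    dta.gamma1.data[...] = 0.5
    dta.gamma2.data[...] = 0.5
    x = rng.standard_normal((1, 8, 3, 3)).astype(np.float32)
    expect = 0.5 * dta.tsa(x).data + 0.5 * dta.gsa(x).data + x
    assert np.allclose(dta(x).data, expect, atol=1e-6)


def test_gated_single_attention_identity_at_init(rng):
    for mod in (GatedAttention(TSA(8, rng=rng)), GatedAttention(GSA(8, rng=rng))):
        x = rng.standard_normal((1, 8, 2, 2)).astype(np.float32)
        assert mod(x).data.tobytes() == x.tobytes()


def test_aspp_preserves_shape(rng):
    aspp = ASPP(16, rng=rng)
    x = rng.standard_normal((1, 16, 8, 8)).astype(np.float32)
    assert aspp(x).shape == (1, 16, 8, 8)
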