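"""A compact reverse-mode automatic-differentiation engine on NumPy arrays.

Every operation the segmentation network needs — dilated/strided convolution,
2x2 transposed convolution, pooling, batch normalization, softmax attention
products and the stabilized binary cross-entropy — is implemented as a
primitive with a hand-written backward pass, recorded on a dynamic tape.

All primitives optionally report their forward floating-point cost to an
active :class:`FlopCounter` (multiply-accumulate counted as 2 FLOPs for
convolutions and matrix products; cheap elementwise ops counted per element).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "no_grad", "FlopCounter", "count_flops",
    "add", "mul", "matmul", "reshape", "transpose", "concat",
    "relu", "sigmoid", "softmax", "mean", "tsum",
    "conv2d", "conv_transpose2x2", "maxpool2x2", "avgpool", "upsample_nearest",
    "batchnorm2d", "bce_with_logits",
]

_GRAD_ENABLED = True
_FLOPS: "FlopCounter | None" = None


class FlopCounter:
    """Accumulates forward-pass floating-point operations."""

    def __init__(self) -> None:
        self.total = 0

    def add(self, n: int) -> None:
        self.total += int(n)


@contextmanager
def count_flops(counter: FlopCounter):
    """Route primitive FLOP counts into *counter* while the context is live."""
    global _FLOPS
    prev, _FLOPS = _FLOPS, counter
    try:
        yield counter
    finally:
        _FLOPS = prev


def _flops(n: int) -> None:
    if _FLOPS is not None:
        _FLOPS.add(n)


@contextmanager
def no_grad():
    """Disable tape recording (evaluation-mode forward passes)."""
    global _GRAD_ENABLED
    prev, _GRAD_ENABLED = _GRAD_ENABLED, False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An n-d array plus an optional gradient and tape linkage."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- introspection ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd --------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -other)

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _make(data, parents, backward) -> Tensor:
    needs = _GRAD_ENABLED and any(
        isinstance(p, Tensor) and p.requires_grad for p in parents
    )
    out = Tensor(data, requires_grad=needs)
    if needs:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum *g* down to *shape* (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Elementwise / linear-algebra primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a = as_tensor(a)
    if not isinstance(b, Tensor):
        out_data = a.data + b
        _flops(out_data.size)
        return _make(out_data, (a,), lambda g: _accum(a, _unbroadcast(g, a.shape)))
    out_data = a.data + b.data
    _flops(out_data.size)

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a = as_tensor(a)
    if not isinstance(b, Tensor):
        out_data = a.data * b
        _flops(out_data.size)
        return _make(out_data, (a,), lambda g: _accum(a, _unbroadcast(g * b, a.shape)))
    out_data = a.data * b.data
    _flops(out_data.size)

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.matmul(a.data, b.data)
    # 2*m*n*k per stacked product
    batch = int(np.prod(out_data.shape[:-2])) if out_data.ndim > 2 else 1
    _flops(2 * batch * out_data.shape[-2] * out_data.shape[-1] * a.data.shape[-1])

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        _accum(a, _unbroadcast(ga, a.shape))
        _accum(b, _unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


def reshape(t: Tensor, shape) -> Tensor:
    t = as_tensor(t)
    in_shape = t.data.shape
    return _make(t.data.reshape(shape), (t,),
                 lambda g: _accum(t, g.reshape(in_shape)))


def transpose(t: Tensor, axes) -> Tensor:
    t = as_tensor(t)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(t.data.transpose(axes), (t,),
                 lambda g: _accum(t, g.transpose(inv)))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, sizes, axis=axis)):
            _accum(t, piece)

    return _make(out_data, tuple(tensors), backward)


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = np.maximum(t.data, 0)
    _flops(out_data.size)
    mask = t.data > 0
    return _make(out_data, (t,), lambda g: _accum(t, g * mask))


def sigmoid(t: Tensor) -> Tensor:
    t = as_tensor(t)
    x = t.data
    s = np.empty_like(x)
    pos = x >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    s[~pos] = ex / (1.0 + ex)
    _flops(4 * s.size)
    return _make(s, (t,), lambda g: _accum(t, g * s * (1.0 - s)))


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    t = as_tensor(t)
    z = t.data - t.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    s = ez / ez.sum(axis=axis, keepdims=True)
    _flops(5 * s.size)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        _accum(t, s * (g - dot))

    return _make(s, (t,), backward)


def tsum(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    t = as_tensor(t)
    out_data = t.data.sum(axis=axis, keepdims=keepdims)
    _flops(t.data.size)
    in_shape = t.data.shape

    def backward(g):
        if axis is None:
            _accum(t, np.broadcast_to(g, in_shape).copy())
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(t, np.broadcast_to(gg, in_shape).copy())

    return _make(out_data, (t,), backward)


def mean(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    t = as_tensor(t)
    n = t.data.size if axis is None else np.prod(
        [t.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(t, axis, keepdims), 1.0 / float(n))


# ---------------------------------------------------------------------------
# Convolution family
# ---------------------------------------------------------------------------

def _windows(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(2, 3))
    return win[:, :, ::stride, ::stride, ::dilation, ::dilation]


def conv2d(x: Tensor, w: Tensor, b: "Tensor | None" = None, stride: int = 1,
           dilation: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, weight (out, in, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cw}")

    if kh == kw == 1 and stride == 1 and padding == 0 and dilation == 1:
        wm = w.data.reshape(O, C)
        out_data = np.tensordot(wm, x.data, axes=([1], [1])).transpose(1, 0, 2, 3)
        if b is not None:
            out_data = out_data + b.data[None, :, None, None]
        _flops(2 * C * O * H * W * B)

        def backward1(g):
            _accum(w, np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))
                   .reshape(w.shape))
            _accum(x, np.tensordot(wm.T, g, axes=([1], [1])).transpose(1, 0, 2, 3))
            if b is not None:
                _accum(b, g.sum(axis=(0, 2, 3)))

        parents = (x, w) if b is None else (x, w, b)
        return _make(out_data, parents, backward1)

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _windows(xp, kh, kw, stride, dilation)  # (B,C,Ho,Wo,kh,kw)
    Ho, Wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wm = w.data.reshape(O, -1)
    out = cols @ wm.T
    out_data = out.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    _flops(2 * kh * kw * C * O * Ho * Wo * B)

    def backward(g):
        go = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        _accum(w, (go.T @ cols).reshape(w.shape))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = go @ wm  # (B*Ho*Wo, C*kh*kw)
            gwin = gcols.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :,
                        i * dilation: i * dilation + Ho * stride: stride,
                        j * dilation: j * dilation + Wo * stride: stride,
                        ] += gwin[:, :, :, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            _accum(x, gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: "Tensor | None" = None) -> Tensor:
    """Transposed convolution, 2x2 kernel, stride 2 (exact 2x upsampling).

    Weight layout (in, out, 2, 2); output blocks do not overlap.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.shape
    Cw, O = w.shape[0], w.shape[1]
    if C != Cw:
        raise ValueError(f"conv_transpose2x2: {C} channels vs weight {Cw}")
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (B,H,W,O,2,2)
    out_data = t.transpose(0, 3, 1, 4, 2, 5).reshape(B, O, 2 * H, 2 * W)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    _flops(2 * C * O * 4 * H * W * B)

    def backward(g):
        gwin = g.reshape(B, O, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)  # (B,H,W,O,2,2)
        _accum(w, np.tensordot(x.data, gwin, axes=([0, 2, 3], [0, 1, 2])))
        _accum(x, np.tensordot(gwin, w.data, axes=([3, 4, 5], [1, 2, 3]))
               .transpose(0, 3, 1, 2))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 requires even spatial size, got {H}x{W}")
    xw = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xw = xw.reshape(B, C, H // 2, W // 2, 4)
    idx = xw.argmax(axis=-1)
    out_data = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
    _flops(x.data.size)

    def backward(g):
        gw = np.zeros((B, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accum(x, gx.reshape(B, C, H, W))

    return _make(out_data, (x,), backward)


def avgpool(x: Tensor, k: int) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"avgpool factor {k} does not divide {H}x{W}")
    out_data = x.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))
    _flops(x.data.size)

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        _accum(x, gx)

    return _make(out_data, (x,), backward)


def upsample_nearest(x: Tensor, k: int) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    out_data = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)
    _flops(out_data.size)

    def backward(g):
        gx = g.reshape(B, C, H, k, W, k).sum(axis=(3, 5))
        _accum(x, gx)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# Normalization and loss
# ---------------------------------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                running_var: np.ndarray, training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization; mutates running stats in training mode."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    n = B * H * W
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        unbiased = var * (n / max(n - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * invstd[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    _flops(2 * x.data.size)

    def backward(g):
        _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gs = gamma.data[None, :, None, None] * invstd[None, :, None, None]
        if training:
            gsum = g.sum(axis=(0, 2, 3), keepdims=True)
            gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = gs * (g - gsum / n - xhat * gxsum / n)
        else:
            gx = gs * g
        _accum(x, gx)

    return _make(out_data, (x, gamma, beta), backward)


def bce_with_logits(logits: Tensor, target: np.ndarray,
                    pos_weight: "float | None" = None) -> Tensor:
    """Mean binary cross-entropy on pre-sigmoid scores, numerically stable.

    ``pos_weight`` multiplies the foreground (target==1) terms.
    """
    logits = as_tensor(logits)
    t = np.asarray(target, dtype=logits.data.dtype)
    if t.shape != logits.shape:
        raise ValueError(f"bce_with_logits: shape {t.shape} vs {logits.shape}")
    uniq = np.unique(t)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("bce_with_logits: ground truth must be binary {0,1}")
    x = logits.data
    pw = 1.0 if pos_weight is None else float(pos_weight)
    softplus_negabs = np.log1p(np.exp(-np.abs(x)))
    # softplus(x) = max(x,0) + log1p(exp(-|x|)); loss = pw*t*sp(-x) + (1-t)*sp(x)
    sp_neg = np.maximum(-x, 0) + softplus_negabs   # softplus(-x) = -log sigmoid(x)
    sp_pos = np.maximum(x, 0) + softplus_negabs    # softplus(x)
    per = pw * t * sp_neg + (1.0 - t) * sp_pos
    n = per.size
    out_data = np.asarray(per.mean(), dtype=x.dtype)
    _flops(8 * n)

    def backward(g):
        s = np.empty_like(x)
        pos = x >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        s[~pos] = ex / (1.0 + ex)
        grad = (pw * t * (s - 1.0) + (1.0 - t) * s) / n
        _accum(logits, g * grad)

    return _make(out_data, (logits,), backward)
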