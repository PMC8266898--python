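"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small define-by-run engine: each operation returns a
:class:`Tensor` that remembers its parents and a closure computing the
vector-Jacobian product. Only the operations needed by encoder/decoder
segmentation networks are provided (2-D dilated convolution, 2x2 stride-2
transposed convolution, 2x2 max-pooling, batch normalization, ReLU,
channel concatenation, elementwise add, mean, sigmoid and a numerically
stable binary cross-entropy with logits).

All convolutions use "same" zero padding at stride 1, so spatial shapes
are preserved; this matches the architecture's contract that only pooling
and transposed convolutions change resolution.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference-only forwards)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """An array node in the autodiff graph.

    Parameters
    ----------
    data : array_like
        Wrapped values; converted to ``float64``.
    requires_grad : bool
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Backpropagate from this node through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=DTYPE)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if id(parent) not in seen:
                    stack.append((parent, False))

        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    # convenience operators (thin wrappers over the functional forms)
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return scale(self, other)

    __rmul__ = __mul__


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad and t._backward is None and not t._prev:
        return
    if t.grad is None:
        t.grad = g.astype(DTYPE, copy=True)
    else:
        t.grad = t.grad + g


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._prev or t._backward is not None for t in tensors)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and _needs_graph(*parents):
        out._prev = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ----------------------------------------------------------------------
# elementwise / structural ops

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def scale(a, c: float) -> Tensor:
    a = as_tensor(a)
    c = float(c)

    def backward(g):
        _accumulate(a, g * c)

    return _make(a.data * c, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accumulate(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    """Piecewise logistic that keeps the far tails (no overflow, no flush to 0/1)."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = _stable_sigmoid(a.data)

    def backward(g):
        _accumulate(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def concat(a, b) -> Tensor:
    """Concatenate two rank-4 tensors along the channel axis."""
    a, b = as_tensor(a), as_tensor(b)
    na = a.data.shape[1]
    data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        _accumulate(a, g[:, :na])
        _accumulate(b, g[:, na:])

    return _make(data, (a, b), backward)


def mean(a) -> Tensor:
    a = as_tensor(a)
    n = a.data.size

    def backward(g):
        _accumulate(a, np.full_like(a.data, float(g) / n))

    return _make(a.data.mean(), (a,), backward)


# ----------------------------------------------------------------------
# convolution family

def conv2d(x, weight, bias=None, dilation: int = 1) -> Tensor:
    """2-D cross-correlation with dilation ``d`` and "same" zero padding.

    ``weight`` has shape (out_channels, in_channels, k, k) with odd ``k``.
    Implemented as a sum over the k*k kernel taps, each a GEMM over the
    channel axis, which keeps memory linear in the input size.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    b, c, h, w = x.data.shape
    o, ci, k, k2 = weight.data.shape
    if k != k2 or k % 2 == 0:
        raise ValueError(f"kernel must be square with odd size, got {k}x{k2}")
    if ci != c:
        raise ValueError(f"input has {c} channels but weight expects {ci}")
    d = int(dilation)
    if d < 1:
        raise ValueError(f"dilation must be a positive integer, got {dilation}")

    p = d * (k - 1) // 2
    # im2col: one contiguous (b, c*k*k, h*w) buffer, then a single batched GEMM
    if p:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    else:
        xp = x.data
    if k == 1:
        cols = xp.reshape(b, c, h * w)
    else:
        cols = np.empty((b, c, k * k, h, w), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                cols[:, :, i * k + j] = xp[:, :, i * d : i * d + h, j * d : j * d + w]
        cols = cols.reshape(b, c * k * k, h * w)
    w2 = weight.data.reshape(o, c * k * k)
    out = np.matmul(w2, cols).reshape(b, o, h, w)
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data.reshape(1, -1, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.reshape(b, o, h * w)
        gw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.data.shape)
        gcols = np.matmul(w2.T, g2)
        if k == 1:
            gx = gcols.reshape(b, c, h, w)
        else:
            gc = gcols.reshape(b, c, k * k, h, w)
            gxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i * d : i * d + h, j * d : j * d + w] += gc[:, :, i * k + j]
            gx = gxp[:, :, p : p + h, p : p + w] if p else gxp
        _accumulate(x, gx)
        _accumulate(weight, gw)
        if bias is not None:
            _accumulate(bias, g.sum(axis=(0, 2, 3)))

    return _make(out, parents, backward)


def conv_transpose2d(x, weight) -> Tensor:
    """2x2 stride-2 transposed convolution (exact spatial doubling).

    ``weight`` has shape (in_channels, out_channels, 2, 2). With kernel
    size equal to stride the output taps never overlap, so each of the
    four sub-grids of the output is one GEMM.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    b, c, h, w = x.data.shape
    ci, o, k, k2 = weight.data.shape
    if (k, k2) != (2, 2):
        raise ValueError("conv_transpose2d supports 2x2 kernels only")
    if ci != c:
        raise ValueError(f"input has {c} channels but weight expects {ci}")

    out = np.empty((b, o, 2 * h, 2 * w), dtype=DTYPE)
    for a in range(2):
        for bb in range(2):
            sub = np.tensordot(x.data, weight.data[:, :, a, bb], axes=([1], [0]))
            out[:, :, a::2, bb::2] = sub.transpose(0, 3, 1, 2)

    def backward(g):
        gx = np.zeros_like(x.data)
        gw = np.empty_like(weight.data)
        for a in range(2):
            for bb in range(2):
                gsub = g[:, :, a::2, bb::2]
                gx += np.tensordot(gsub, weight.data[:, :, a, bb], axes=([1], [1])).transpose(
                    0, 3, 1, 2
                )
                gw[:, :, a, bb] = np.tensordot(x.data, gsub, axes=([0, 2, 3], [0, 2, 3]))
        _accumulate(x, gx)
        _accumulate(weight, gw)

    return _make(out, (x, weight), backward)


def max_pool2d(x) -> Tensor:
    """2x2 stride-2 max pooling; spatial dims must be even."""
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d needs even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    windows = (
        x.data.reshape(b, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
    )
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        g4 = np.zeros((b, c, h2, w2, 4), dtype=DTYPE)
        np.put_along_axis(g4, idx[..., None], g[..., None], axis=-1)
        gx = g4.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)
        _accumulate(x, gx)

    return _make(out, (x,), backward)


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (batch, H, W).

    In training mode normalizes with batch statistics and updates the
    running estimates in place; in evaluation mode uses the running
    (frozen) statistics, which makes forward passes deterministic.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    c = x.data.shape[1]
    gview = gamma.data.reshape(1, c, 1, 1)

    if training:
        m = x.data.size // c
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        unbiased = var * (m / max(m - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu = running_mean
        var = running_var

    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * ivstd.reshape(1, c, 1, 1)
    out = gview * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accumulate(beta, g.sum(axis=(0, 2, 3)))
        dxhat = g * gview
        iv = ivstd.reshape(1, c, 1, 1)
        if training:
            m = x.data.size // c
            sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (iv / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        else:
            gx = dxhat * iv
        _accumulate(x, gx)

    return _make(out, (x, gamma, beta), backward)


def bce_with_logits(logits, targets) -> Tensor:
    """Mean binary cross-entropy computed from raw logits.

    Uses the log-sum-exp form ``max(z,0) - z*y + log1p(exp(-|z|))`` which
    is stable for large |z|; the gradient is ``(sigmoid(z) - y) / n``.
    """
    logits = as_tensor(logits)
    y = np.asarray(targets, dtype=DTYPE)
    if y.shape != logits.data.shape:
        raise ValueError(f"target shape {y.shape} != logit shape {logits.data.shape}")
    z = logits.data
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        s = _stable_sigmoid(z)
        _accumulate(logits, float(g) * (s - y) / n)

    return _make(loss.mean(), (logits,), backward)
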