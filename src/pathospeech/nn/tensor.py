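"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operations the spectrogram CNN needs
(3x3/7x7 same-padding convolutions via im2col + BLAS matmul, 2x2 max
pooling, block average pooling, channel/spatial reductions for the
attention module, batch normalization, fully connected layers and a
softmax cross-entropy loss).  Tensors record their parents on a tape;
``Tensor.backward`` runs a topological sweep.  Dtype follows the input
arrays (float32 for training-scale work, float64 for gradient checks).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor", "no_grad", "add", "mul", "scale", "matmul", "relu", "sigmoid",
    "conv2d", "maxpool2x2", "avgpool", "global_avgpool", "spatial_max",
    "channel_mean", "channel_max", "concat", "reshape",
    "batchnorm_train", "batchnorm_eval", "softmax", "softmax_cross_entropy",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference); saves memory and time."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "retain_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.retain_grad = False
        self.grad = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: activation graphs are deep
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            is_leaf = node._backward is None
            if (node.requires_grad and is_leaf) or node.retain_grad:
                node.grad = g if node.grad is None else node.grad + g
            if not is_leaf:
                for parent, pg in node._backward(g):
                    if not _needs(parent):
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    # convenience arithmetic on tensors / scalars
    def __add__(self, other):
        return add(self, other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.dtype)))

    def __mul__(self, other):
        if isinstance(other, Tensor):
            return mul(self, other)
        return scale(self, float(other))

    __rmul__ = __mul__


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], list[tuple[Tensor, np.ndarray]]]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(_needs(p) for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _needs(t: Tensor) -> bool:
    return t.requires_grad or t._backward is not None


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return [(a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape))]
    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return [(a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape))]
    return _make(a.data * b.data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        return [(a, g * s)]
    return _make(a.data * s, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return [(a, g @ b.data.T), (b, a.data.T @ g)]
    return _make(a.data @ b.data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    def backward(g):
        return [(a, g * mask)]
    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))
    def backward(g):
        return [(a, g * out * (1.0 - out))]
    return _make(out, (a,), backward)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    old = a.data.shape
    def backward(g):
        return [(a, g.reshape(old))]
    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return list(zip(tensors, pieces))
    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


# ---------------------------------------------------------------------
# convolution (stride 1, same padding)
#
# Feature maps use NHWC layout (N, H, W, C).  A k x k convolution is
# computed as k*k shifted rank-C gemms accumulated into the output:
# out(n,y,x,:) = sum_ij  x_pad(n,y+i,x+j,:) @ W[i,j].  All reads and
# writes touch contiguous (row, channel) blocks, which on CPU beats an
# explicit im2col materialization by a wide margin.
# ---------------------------------------------------------------------

def _pad_spatial(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    n, h, w, c = x.shape
    xp = np.zeros((n, h + 2 * ph, w + 2 * pw, c), dtype=x.dtype)
    xp[:, ph:ph + h, pw:pw + w, :] = x
    return xp


def _conv_padded(xp: np.ndarray, kern: np.ndarray, h: int, wd: int) -> np.ndarray:
    """Convolve a pre-padded input; output is (N, h, wd, Cout)."""
    n, hp, wp, ci = xp.shape
    kh, kw, _, co = kern.shape
    if ci * 4 <= kh * kw:
        # few input channels: one patch gemm beats kh*kw skinny gemms
        col = _im2col(xp, kh, kw, h, wd)
        return (col @ kern.reshape(-1, co)).reshape(n, h, wd, co)
    xp_flat = xp.reshape(-1, ci)
    out = np.zeros((n, h, wd, co), dtype=xp.dtype)
    zbuf = np.empty((n * hp * wp, co), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            np.matmul(xp_flat, kern[i, j], out=zbuf)
            out += zbuf.reshape(n, hp, wp, co)[:, i:i + h, j:j + wd, :]
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, h: int, wd: int) -> np.ndarray:
    n, _, _, ci = xp.shape
    col = np.empty((n, h, wd, kh * kw, ci), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            col[:, :, :, i * kw + j, :] = xp[:, i:i + h, j:j + wd, :]
    return col.reshape(n * h * wd, kh * kw * ci)


def _conv_raw(x: np.ndarray, kern: np.ndarray) -> np.ndarray:
    kh, kw = kern.shape[:2]
    xp = _pad_spatial(x, kh // 2, kw // 2)
    return _conv_padded(xp, kern, x.shape[1], x.shape[2])


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 same-padding 2-D convolution (cross-correlation).

    ``x``: (N, H, W, Cin); ``w``: (kh, kw, Cin, Cout); ``b``: (Cout,).
    """
    kh, kw, ci, co = w.data.shape
    n, h, wd, _ = x.data.shape
    xp = _pad_spatial(x.data, kh // 2, kw // 2)
    out = _conv_padded(xp, w.data, h, wd)
    if b is not None:
        out += b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g_mat = g.reshape(-1, co)
        grads = []
        if _needs(x):
            # gradient wrt input: full correlation with flipped transposed kernel
            wf = np.ascontiguousarray(w.data[::-1, ::-1].transpose(0, 1, 3, 2))
            grads.append((x, _conv_raw(g, wf)))
        if _needs(w):
            dw = np.empty((kh, kw, ci, co), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    patch = np.ascontiguousarray(xp[:, i:i + h, j:j + wd, :]).reshape(-1, ci)
                    dw[i, j] = patch.T @ g_mat
            grads.append((w, dw))
        if b is not None:
            grads.append((b, g_mat.sum(axis=0)))
        return grads

    return _make(out, parents, backward)


# ---------------------------------------------------------------------
# pooling and reductions (NHWC)
# ---------------------------------------------------------------------

def maxpool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    r = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    out = r.max(axis=(2, 4))

    def backward(g):
        mask = r == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True, dtype=g.dtype)
        dx = mask * (g[:, :, None, :, None, :] / counts)
        return [(x, dx.reshape(n, h, w, c))]

    return _make(out, (x,), backward)


def avgpool(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling (k divides H and W)."""
    n, h, w, c = x.data.shape
    r = x.data.reshape(n, h // k, k, w // k, k, c)
    out = r.mean(axis=(2, 4))

    def backward(g):
        dx = np.broadcast_to(g[:, :, None, :, None, :] / (k * k),
                             (n, h // k, k, w // k, k, c))
        return [(x, dx.reshape(n, h, w, c))]

    return _make(out, (x,), backward)


def global_avgpool(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    out = x.data.mean(axis=(1, 2))

    def backward(g):
        dx = np.broadcast_to(g[:, None, None, :] / (h * w), (n, h, w, c))
        return [(x, np.ascontiguousarray(dx))]

    return _make(out, (x,), backward)


def spatial_max(x: Tensor) -> Tensor:
    """(N, H, W, C) -> (N, C): maximum over the spatial extent."""
    out = x.data.max(axis=(1, 2))

    def backward(g):
        mask = x.data == out[:, None, None, :]
        counts = mask.sum(axis=(1, 2), keepdims=True, dtype=g.dtype)
        return [(x, mask * (g[:, None, None, :] / counts))]

    return _make(out, (x,), backward)


def channel_mean(x: Tensor) -> Tensor:
    c = x.data.shape[-1]
    out = x.data.mean(axis=-1, keepdims=True)

    def backward(g):
        return [(x, np.broadcast_to(g / c, x.data.shape).copy())]

    return _make(out, (x,), backward)


def channel_max(x: Tensor) -> Tensor:
    out = x.data.max(axis=-1, keepdims=True)

    def backward(g):
        mask = x.data == out
        counts = mask.sum(axis=-1, keepdims=True, dtype=g.dtype)
        return [(x, mask * (g / counts))]

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------
# batch normalization (NHWC: per-channel over N, H, W)
# ---------------------------------------------------------------------

def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """BN over (N, H, W) per channel. Returns (out, batch_mean, batch_var)."""
    xd = x.data
    axes = (0, 1, 2)
    m = xd.shape[0] * xd.shape[1] * xd.shape[2]
    mean = xd.mean(axis=axes)
    var = xd.var(axis=axes)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean) * ivar
    out = xhat * gamma.data + beta.data

    def backward(g):
        # sum(dxhat) = gamma*dbeta and sum(dxhat*xhat) = gamma*dgamma, so the
        # standard BN input gradient needs only these two reductions.
        gf = g.reshape(-1, g.shape[-1])
        xf = xhat.reshape(-1, g.shape[-1])
        dbeta = gf.sum(axis=0)
        dgamma = np.einsum("nc,nc->c", gf, xf, optimize=True)
        k = gamma.data * ivar / m
        dx = k * (m * g - dbeta - xhat * dgamma)
        return [(x, dx), (gamma, dgamma), (beta, dbeta)]

    return _make(out, (x, gamma, beta), backward), mean, var


def batchnorm_eval(x: Tensor, gamma: Tensor, beta: Tensor,
                   running_mean: np.ndarray, running_var: np.ndarray,
                   eps: float = 1e-5) -> Tensor:
    ivar = (1.0 / np.sqrt(running_var + eps)).astype(x.dtype)
    xhat = (x.data - running_mean) * ivar
    out = xhat * gamma.data + beta.data

    def backward(g):
        dx = g * (gamma.data * ivar)
        return [(x, dx), (gamma, (g * xhat).sum(axis=(0, 1, 2))),
                (beta, g.sum(axis=(0, 1, 2)))]

    return _make(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------
# classification head helpers
# ---------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), labels].mean()
    probs = np.exp(logp)

    def backward(g):
        dl = probs.copy()
        dl[np.arange(n), labels] -= 1.0
        return [(logits, dl * (g / n))]

    return _make(np.asarray(loss, dtype=logits.dtype), (logits,), backward)
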