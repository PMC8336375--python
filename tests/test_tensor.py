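"""Finite-difference checks of the reverse-mode array operations."""

from __future__ import annotations

import numpy as np
import pytest

from pathospeech.nn import tensor as T
from pathospeech.nn.tensor import Tensor


def _numeric_grad(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def _check(op, shapes, seed=0, atol=1e-6):
    """Backprop of a scalar projection of ``op`` matches finite differences."""
    rng = np.random.default_rng(seed)
    arrays = [rng.standard_normal(s) for s in shapes]
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    out = op(*tensors)
    w = rng.standard_normal(out.shape)

    def scalar():
        with T.no_grad():
            return float((op(*[Tensor(a) for a in arrays]).data * w).sum())

    out.backward(w)
    for a, t in zip(arrays, tensors):
        num = _numeric_grad(scalar, a)
        np.testing.assert_allclose(t.grad, num, atol=atol,
                                   err_msg=f"gradient mismatch for shape {a.shape}")


def test_elementwise_and_matmul_gradients():
    _check(T.add, [(3, 4), (3, 4)])
    _check(T.mul, [(3, 4), (3, 4)])
    _check(lambda a: T.scale(a, 2.5), [(3, 4)])
    _check(T.relu, [(5, 6)], seed=1)
    _check(T.sigmoid, [(5, 6)])
    _check(T.matmul, [(4, 3), (3, 5)])
    _check(lambda a: T.reshape(a, (2, 6)), [(3, 4)])
    _check(lambda a, b: T.concat([a, b], axis=1), [(2, 3), (2, 4)])


def test_convolution_gradients_both_paths():
    # few input channels exercise the shifted-product path; a single
    # channel exercises the patch-matrix path
    _check(lambda x, w, b: T.conv2d(x, w, b),
           [(2, 5, 6, 3), (3, 3, 3, 4), (4,)], atol=1e-5)
    _check(lambda x, w, b: T.conv2d(x, w, b),
           [(1, 6, 7, 1), (3, 3, 1, 2), (2,)], atol=1e-5)
    _check(lambda x, w: T.conv2d(x, w),
           [(1, 8, 8, 2), (7, 7, 2, 1)], atol=1e-5)


def test_pooling_gradients():
    _check(T.maxpool2x2, [(2, 4, 6, 3)], seed=3, atol=1e-5)
    _check(lambda x: T.avgpool(x, 2), [(2, 4, 6, 3)])
    _check(T.global_avgpool, [(2, 4, 6, 3)])
    _check(T.spatial_max, [(2, 4, 6, 3)], seed=4, atol=1e-5)
    _check(T.channel_mean, [(2, 4, 6, 3)])
    _check(T.channel_max, [(2, 4, 6, 3)], seed=5, atol=1e-5)


def test_batchnorm_gradients():
    rng = np.random.default_rng(9)
    x = rng.standard_normal((4, 3, 5, 2))
    gamma = rng.standard_normal(2)
    beta = rng.standard_normal(2)

    def op(xt, gt, bt):
        out, *_ = T.batchnorm_train(xt, gt, bt)
        return out

    _check(op, [(4, 3, 5, 2), (2,), (2,)], seed=9, atol=1e-5)
    _check(lambda xt, gt, bt: T.batchnorm_eval(
        xt, gt, bt, np.zeros(2), np.ones(2)), [(4, 3, 5, 2), (2,), (2,)])


def test_cross_entropy_gradient_and_value():
    rng = np.random.default_rng(2)
    logits = rng.standard_normal((6, 2))
    labels = rng.integers(0, 2, size=6)
    t = Tensor(logits, requires_grad=True)
    loss = T.softmax_cross_entropy(t, labels)
    # value: mean negative log softmax probability of the true class
    p = T.softmax(logits, axis=1)
    expected = -np.mean(np.log(p[np.arange(6), labels]))
    assert float(loss.data) == pytest.approx(expected, abs=1e-10)

    loss.backward()
    eps = 1e-6
    for i in range(6):
        for j in range(2):
            pert = logits.copy()
            pert[i, j] += eps
            with T.no_grad():
                hi = float(T.softmax_cross_entropy(Tensor(pert), labels).data)
            pert[i, j] -= 2 * eps
            with T.no_grad():
                lo = float(T.softmax_cross_entropy(Tensor(pert), labels).data)
            assert t.grad[i, j] == pytest.approx((hi - lo) / (2 * eps), abs=1e-6)


def test_no_grad_suppresses_graph():
    x = Tensor(np.ones((2, 2)), requires_grad=True)
    with T.no_grad():
        y = T.relu(x)
    assert not y.requires_grad


def test_backward_accumulates_across_reuse():
    x = Tensor(np.array([[2.0, -1.0]]), requires_grad=True)
    y = T.add(T.mul(x, x), x)       # x^2 + x -> grad 2x + 1
    y.backward(np.ones_like(y.data))
    np.testing.assert_allclose(x.grad, [[5.0, -1.0]])
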