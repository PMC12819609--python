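"""Autodiff engine: gradients against numerical differentiation, conv and
resize against independent references, optimizer/scheduler behavior."""

import numpy as np
import pytest

from afcnet.nd import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ReduceLROnPlateau,
    Tensor,
    bilinear_resize,
    concat,
    conv2d,
    count_params,
    seed_all,
)
from afcnet.nd.modules import Parameter

from _oracle import bilinear_ref, conv2d_brute


def numerical_grad(fn, x, eps=1e-6):
    g = np.zeros_like(x.data)
    flat = x.data.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        up = fn().item()
        flat[i] = orig - eps
        dn = fn().item()
        flat[i] = orig
        gflat[i] = (up - dn) / (2 * eps)
    return g


@pytest.mark.parametrize("op", ["mul", "div", "relu", "sigmoid", "tanh", "abs", "log", "sqrt"])
def test_elementwise_gradients(rng, op):
    x = Tensor(rng.uniform(0.2, 2.0, size=(3, 4)), requires_grad=True)
    y = Tensor(rng.uniform(0.2, 2.0, size=(3, 4)), requires_grad=True)
    ops = {
        "mul": lambda: (x * y).sum(),
        "div": lambda: (x / y).sum(),
        "relu": lambda: ((x - 1.0).relu() * y).sum(),
        "sigmoid": lambda: (x.sigmoid() * y).sum(),
        "tanh": lambda: (x.tanh() * y).sum(),
        "abs": lambda: ((x - 1.0).abs() * y).sum(),
        "log": lambda: (x.log() * y).sum(),
        "sqrt": lambda: (x.sqrt() * y).sum(),
    }
    fn = ops[op]
    out = fn()
    out.backward()
    assert np.allclose(x.grad, numerical_grad(fn, x), atol=1e-5)
    assert np.allclose(y.grad, numerical_grad(fn, y), atol=1e-5)


def test_broadcast_gradients(rng):
    x = Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)
    b = Tensor(rng.normal(size=(1, 3, 1)), requires_grad=True)
    fn = lambda: ((x * b + b) ** 2).sum()
    fn().backward()
    assert np.allclose(b.grad, numerical_grad(fn, b), atol=1e-5)


def test_mean_sum_axis_gradients(rng):
    x = Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)
    fn = lambda: (x.mean(axis=(0, 2), keepdims=True) * x).sum()
    fn().backward()
    assert np.allclose(x.grad, numerical_grad(fn, x), atol=1e-5)


@pytest.mark.parametrize("groups,stride", [(1, 1), (1, 2), (2, 1), (4, 1)])
def test_conv2d_matches_brute_force(rng, groups, stride):
    x = Tensor(rng.normal(size=(2, 4, 6, 7)), requires_grad=True)
    w = Tensor(rng.normal(size=(4, 4 // groups, 3, 3)), requires_grad=True)
    b = Tensor(rng.normal(size=4), requires_grad=True)
    out = conv2d(x, w, b, stride=stride, padding=(1, 1), groups=groups)
    ref = conv2d_brute(x.data, w.data, b.data, padding=(1, 1), groups=groups)
    assert np.allclose(out.data, ref[:, :, ::stride, ::stride], atol=1e-10)


def test_conv2d_gradients(rng):
    x = Tensor(rng.normal(size=(1, 2, 5, 5)), requires_grad=True)
    w = Tensor(rng.normal(size=(3, 2, 3, 3)), requires_grad=True)
    b = Tensor(rng.normal(size=3), requires_grad=True)
    fn = lambda: (conv2d(x, w, b, padding=(1, 1)) ** 2).sum()
    fn().backward()
    for t in (x, w, b):
        assert np.allclose(t.grad, numerical_grad(fn, t), atol=1e-4)


def test_depthwise_conv_gradients(rng):
    x = Tensor(rng.normal(size=(1, 3, 5, 5)), requires_grad=True)
    w = Tensor(rng.normal(size=(3, 1, 1, 3)), requires_grad=True)
    fn = lambda: (conv2d(x, w, padding=(0, 1), groups=3) ** 2).sum()
    fn().backward()
    assert np.allclose(x.grad, numerical_grad(fn, x), atol=1e-4)
    assert np.allclose(w.grad, numerical_grad(fn, w), atol=1e-4)


def test_bilinear_matches_reference(rng):
    x = Tensor(rng.normal(size=(1, 2, 5, 7)))
    for oh, ow in [(10, 14), (3, 4), (5, 7), (20, 28)]:
        assert np.allclose(bilinear_resize(x, oh, ow).data, bilinear_ref(x.data, oh, ow), atol=1e-12)


def test_bilinear_preserves_constants():
    x = Tensor(np.full((1, 1, 22, 22), 3.25))
    y = bilinear_resize(x, 44, 44)
    assert y.shape == (1, 1, 44, 44)
    assert np.allclose(y.data, 3.25, atol=1e-12)


def test_bilinear_gradients(rng):
    x = Tensor(rng.normal(size=(1, 1, 4, 4)), requires_grad=True)
    fn = lambda: (bilinear_resize(x, 7, 9) ** 2).sum()
    fn().backward()
    assert np.allclose(x.grad, numerical_grad(fn, x), atol=1e-5)


def test_concat_gradients(rng):
    a = Tensor(rng.normal(size=(1, 2, 3, 3)), requires_grad=True)
    b = Tensor(rng.normal(size=(1, 3, 3, 3)), requires_grad=True)
    fn = lambda: (concat([a, b], axis=1) ** 2).sum()
    fn().backward()
    assert np.allclose(a.grad, numerical_grad(fn, a), atol=1e-5)
    assert np.allclose(b.grad, numerical_grad(fn, b), atol=1e-5)


def test_batchnorm_gradients_train_mode(rng):
    bn = BatchNorm2d(3)
    x = Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
    weights = np.random.default_rng(0).normal(size=(2, 3, 4, 4))
    fn = lambda: (bn(x) * Tensor(weights)).sum()
    fn().backward()
    assert np.allclose(x.grad, numerical_grad(fn, x), atol=1e-4)
    assert np.allclose(bn.gamma.grad, numerical_grad(fn, bn.gamma), atol=1e-4)


def test_batchnorm_eval_uses_running_stats(rng):
    bn = BatchNorm2d(2)
    x = Tensor(rng.normal(size=(4, 2, 3, 3)) * 5 + 2)
    bn(x)  # one train-mode pass updates running stats
    bn.eval()
    y1 = bn(x)
    y2 = bn(x)
    assert np.array_equal(y1.data, y2.data)


def test_count_params_examples():
    # dense 10 -> 5 with bias, expressed as a 1x1 conv: 55
    assert count_params(Conv2d(10, 5, 1, padding=(0, 0))) == 55
    # 3x3 conv 4 -> 8 with bias: 296
    assert count_params(Conv2d(4, 8, 3)) == 296


def test_count_params_manual_enumeration():
    from afcnet.nd import Module

    class Toy(Module):
        def __init__(self):
            super().__init__()
            self.a = Conv2d(2, 3, 3)
            self.b = BatchNorm2d(3)

    toy = Toy()
    manual = (3 * 2 * 3 * 3 + 3) + (3 + 3)  # conv w+b, bn gamma+beta
    assert count_params(toy) == manual


def test_seeded_init_is_deterministic():
    seed_all(7)
    c1 = Conv2d(3, 4, 3)
    seed_all(7)
    c2 = Conv2d(3, 4, 3)
    assert np.array_equal(c1.weight.data, c2.weight.data)


def test_adam_minimizes_quadratic():
    p = Parameter(np.array([5.0]))
    opt = Adam([p], lr=0.1)
    for _ in range(200):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert abs(p.data[0]) < 1e-2


def test_plateau_scheduler_halves_lr():
    p = Parameter(np.zeros(1))
    opt = Adam([p], lr=1.0)
    sched = ReduceLROnPlateau(opt, factor=0.5, patience=2, min_lr=0.1)
    for _ in range(10):
        sched.step(1.0)  # never improves
    assert opt.lr < 1.0
    for _ in range(100):
        sched.step(1.0)
    assert opt.lr == pytest.approx(0.1)


def test_state_dict_roundtrip(rng):
    seed_all(0)
    bn = BatchNorm2d(3)
    bn(Tensor(rng.normal(size=(2, 3, 4, 4))))
    state = bn.state_dict()
    seed_all(99)
    bn2 = BatchNorm2d(3)
    bn2.load_state_dict(state)
    assert np.array_equal(bn2.running_mean, bn.running_mean)
    assert np.array_equal(bn2.gamma.data, bn.gamma.data)
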