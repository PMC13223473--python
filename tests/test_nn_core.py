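"""Checks of the autodiff compute core against independent references.

Convolution adjoints are verified with dot-product (transpose) identities in
float64-free exact arithmetic on the operators themselves, and forwards are
verified against explicit loop references; elementwise gradients are checked
against hand derivatives.
"""

import numpy as np
import pytest

import nodseg.nn._conv_kernels as _ck
from nodseg import nn
from nodseg.nn import Tensor, autograd as ag
from nodseg.nn.optim import Adam, AdamW, RAdam

import oracles


@pytest.mark.parametrize("xs,ws,dil,pad,groups", [
    ((2, 3, 4, 5, 5), (4, 3, 3, 3, 3), (1, 1, 1), (1, 1, 1), 1),
    ((1, 2, 5, 6, 6), (3, 2, 3, 3, 3), (2, 2, 2), (2, 2, 2), 1),
    ((1, 4, 4, 4, 4), (6, 2, 3, 3, 3), (1, 1, 1), (1, 1, 1), 2),
    ((1, 4, 3, 6, 6), (4, 1, 3, 3, 3), (3, 3, 3), (3, 3, 3), 4),
    ((1, 2, 4, 6, 6), (3, 2, 1, 3, 3), (1, 1, 1), (0, 1, 1), 1),
])
def test_conv3d_adjoint_identities(rng, xs, ws, dil, pad, groups):
    """<gy, A dx> == <A^T gy, dx> for the input map and the weight map."""
    x = rng.normal(size=xs)
    w = rng.normal(size=ws)
    dx = rng.normal(size=xs)
    y = ag._conv3d_forward(dx.astype(np.float32), w.astype(np.float32),
                           None, dil, pad, groups)
    gy = rng.normal(size=y.shape).astype(np.float32)
    lhs = float((gy * y).sum())
    gx = ag._conv3d_input_grad(gy, w.astype(np.float32), xs, dil, pad, groups)
    rhs = float((gx * dx).sum())
    assert lhs == pytest.approx(rhs, rel=1e-4)

    dw = rng.normal(size=ws)
    y2 = ag._conv3d_forward(x.astype(np.float32), dw.astype(np.float32),
                            None, dil, pad, groups)
    lhs2 = float((gy * y2).sum())
    gw = ag._conv3d_weight_grad(x.astype(np.float32), gy, ws, dil, pad, groups)
    rhs2 = float((gw * dw).sum())
    assert lhs2 == pytest.approx(rhs2, rel=1e-4)


def test_conv3d_forward_matches_loop_reference(rng):
    x = rng.normal(size=(2, 5, 6, 6)).astype(np.float32)
    w = rng.normal(size=(3, 2, 3, 3, 3)).astype(np.float32)
    got = ag._conv3d_forward(x[None], w, None, (2, 2, 2), (2, 2, 2), 1)[0]
    want = oracles.conv3d_loops(x, w, dilation=(2, 2, 2))
    assert np.abs(got - want).max() < 1e-5


def test_numba_and_fallback_paths_agree(rng):
    if not _ck.HAVE_NUMBA:
        pytest.skip("numba kernels not active")
    x = rng.normal(size=(2, 4, 4, 6, 6)).astype(np.float32)
    w = rng.normal(size=(6, 2, 3, 3, 3)).astype(np.float32)
    gy = rng.normal(size=(2, 6, 4, 6, 6)).astype(np.float32)
    args = ((2, 2, 2), (2, 2, 2), 2)
    y_fast = ag._conv3d_forward(x, w, None, *args)
    gw_fast = ag._conv3d_weight_grad(x, gy, w.shape, *args)
    _ck.HAVE_NUMBA = False
    try:
        y_slow = ag._conv3d_forward(x, w, None, *args)
        gw_slow = ag._conv3d_weight_grad(x, gy, w.shape, *args)
    finally:
        _ck.HAVE_NUMBA = True
    assert np.abs(y_fast - y_slow).max() < 1e-4
    assert np.abs(gw_fast - gw_slow).max() < 1e-3


def test_maxpool_halves_and_routes_gradient(rng):
    x = Tensor(rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32),
               requires_grad=True)
    y = nn.maxpool3d_2(x)
    assert y.shape == (1, 2, 2, 2, 2)
    assert np.allclose(y.numpy(),
                       x.numpy().reshape(1, 2, 2, 2, 2, 2, 2, 2)
                       .max(axis=(3, 5, 7)))
    y.sum().backward()
    # gradient mass is conserved: one unit per pooled window
    assert x.grad.sum() == pytest.approx(y.numpy().size)
    with pytest.raises(ValueError):
        nn.maxpool3d_2(Tensor(np.zeros((1, 1, 3, 4, 4), dtype=np.float32)))


def test_trilinear_upsample_properties(rng):
    x = rng.normal(size=(1, 2, 3, 4, 4)).astype(np.float32)
    y = nn.upsample_trilinear_2(Tensor(x)).numpy()
    assert y.shape == (1, 2, 6, 8, 8)
    # constant fields stay constant; values stay inside the input hull
    c = nn.upsample_trilinear_2(Tensor(np.full((1, 1, 2, 2, 2), 3.25,
                                               dtype=np.float32))).numpy()
    assert np.allclose(c, 3.25)
    assert y.max() <= x.max() + 1e-6 and y.min() >= x.min() - 1e-6
    # adjoint identity
    xt = Tensor(x, requires_grad=True)
    out = nn.upsample_trilinear_2(xt)
    gy = rng.normal(size=out.shape).astype(np.float32)
    (out * Tensor(gy)).sum().backward()
    lhs = float((out.numpy() * gy).sum())
    rhs = float((xt.grad * x).sum())
    assert lhs == pytest.approx(rhs, rel=1e-4)


def test_batchnorm_normalizes_and_tracks_running_stats(rng):
    bn = nn.BatchNorm3d(3, momentum=0.5)
    x = rng.normal(2.0, 3.0, size=(4, 3, 4, 4, 4)).astype(np.float32)
    y = bn(Tensor(x)).numpy()
    assert np.abs(y.mean(axis=(0, 2, 3, 4))).max() < 1e-4
    assert np.abs(y.std(axis=(0, 2, 3, 4)) - 1.0).max() < 1e-3
    bn.eval()
    y2 = bn(Tensor(x)).numpy()
    assert not np.allclose(y, y2)   # eval uses running, not batch, stats


def test_elementwise_gradients_match_hand_derivatives(rng):
    x = Tensor(rng.uniform(0.2, 2.0, size=(5,)).astype(np.float32),
               requires_grad=True)
    y = (x.sigmoid().log() * x ** 2).sum()
    y.backward()
    v = x.numpy().astype(np.float64)
    s = 1 / (1 + np.exp(-v))
    want = 2 * v * np.log(s) + v ** 2 * (1 - s)
    assert np.abs(x.grad - want).max() < 1e-4


def test_broadcast_gradient_reduction(rng):
    a = Tensor(rng.normal(size=(3, 1)).astype(np.float32), requires_grad=True)
    b = Tensor(rng.normal(size=(1, 4)).astype(np.float32), requires_grad=True)
    (a * b).sum().backward()
    assert a.grad.shape == (3, 1) and b.grad.shape == (1, 4)
    assert np.allclose(a.grad[:, 0], b.numpy().sum())


def test_grad_accumulates_across_multiple_uses(rng):
    x = Tensor(np.array([2.0], dtype=np.float32), requires_grad=True)
    y = x * x + x * 3.0
    y.sum().backward()
    assert x.grad[0] == pytest.approx(2 * 2.0 + 3.0)


def test_no_grad_builds_no_graph(rng):
    x = Tensor(rng.normal(size=(4,)).astype(np.float32), requires_grad=True)
    with nn.no_grad():
        y = (x * 2.0).sum()
    assert y._prev == () and y._backward is None


def test_module_state_dict_roundtrip(rng):
    lin = nn.Sequential(nn.Conv3d(2, 3, 3, rng=rng), nn.BatchNorm3d(3))
    state = lin.state_dict()
    lin2 = nn.Sequential(nn.Conv3d(2, 3, 3, rng=rng), nn.BatchNorm3d(3))
    lin2.load_state_dict(state)
    for (k1, p1), (k2, p2) in zip(lin.named_parameters(),
                                  lin2.named_parameters()):
        assert k1 == k2 and np.array_equal(p1.data, p2.data)


@pytest.mark.parametrize("cls", [Adam, AdamW, RAdam])
def test_optimizers_descend_quadratic(cls):
    w = Tensor(np.array([5.0, -3.0], dtype=np.float32), requires_grad=True)
    opt = cls([w], lr=0.1)
    for _ in range(200):
        loss = (w * w).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(w.numpy()).max() < 0.05


def test_adamw_decay_is_decoupled():
    """At zero gradient AdamW shrinks a weight by exactly lr*wd*w, while
    Adam (decay folded into the gradient) steps through the adaptive
    denominator and moves much further."""
    wa = Tensor(np.array([1.0], dtype=np.float32), requires_grad=True)
    opt = AdamW([wa], lr=0.01, weight_decay=0.1)
    wa.grad = np.zeros(1, dtype=np.float32)
    opt.step()
    assert float(wa.numpy()[0]) == pytest.approx(1.0 - 0.01 * 0.1, abs=1e-7)

    wb = Tensor(np.array([1.0], dtype=np.float32), requires_grad=True)
    opt2 = Adam([wb], lr=0.01, weight_decay=0.1)
    wb.grad = np.zeros(1, dtype=np.float32)
    opt2.step()
    assert float(wb.numpy()[0]) == pytest.approx(1.0 - 0.01, rel=1e-3)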