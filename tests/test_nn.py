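"""Layers and training loops: oracles and numeric gradient checks."""

import numpy as np
import pytest
from scipy import ndimage

from cmraudit.nn import (
    ClassifierConfig,
    GroupClassifier,
    SegmenterConfig,
    UNetSegmenter,
    fit_classifier,
    fit_segmenter,
)
from cmraudit.nn.layers import (
    BatchNorm2d,
    Conv2d,
    Linear,
    ReLU,
    Upsample2x,
    bce_with_logits,
    dice_ce_loss,
    sigmoid,
    softmax,
)

RNG = np.random.default_rng(0)


def test_conv_forward_matches_scipy_correlate():
    conv = Conv2d(2, 3, k=3, stride=1, rng=np.random.default_rng(1))
    x = RNG.normal(size=(2, 7, 6, 2)).astype(np.float32)
    y = conv.forward(x)
    for n in range(2):
        for co in range(3):
            ref = sum(
                ndimage.correlate(
                    x[n, :, :, ci].astype(np.float64),
                    conv.w[:, :, ci, co].astype(np.float64),
                    mode="constant",
                )
                for ci in range(2)
            ) + conv.b[co]
            assert np.allclose(y[n, :, :, co], ref, atol=1e-4)


def test_conv_stride_two_shape():
    conv = Conv2d(1, 2, k=3, stride=2, rng=np.random.default_rng(1))
    y = conv.forward(RNG.normal(size=(1, 8, 8, 1)).astype(np.float32))
    assert y.shape == (1, 4, 4, 2)


def _numeric_input_grad(fn, x, r, eps=1e-3):
    """Central-difference gradient of sum(fn(x) * r) at a few entries."""
    g = np.zeros_like(x, dtype=np.float64)
    flat_idx = np.random.default_rng(2).choice(x.size, size=12, replace=False)
    for i in flat_idx:
        idx = np.unravel_index(i, x.shape)
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (np.sum(fn(xp) * r) - np.sum(fn(xm) * r)) / (2 * eps)
    return g, flat_idx


def _check_grad(layer, shape):
    x = RNG.normal(size=shape).astype(np.float32)
    r = RNG.normal(size=layer.forward(x.copy(), train=True).shape).astype(np.float32)
    analytic = layer.backward(r.copy())
    num, idx = _numeric_input_grad(lambda z: layer.forward(z, train=True), x, r)
    for i in idx:
        ii = np.unravel_index(i, x.shape)
        assert analytic[ii] == pytest.approx(num[ii], rel=0.05, abs=2e-3)


def test_conv_input_gradient():
    _check_grad(Conv2d(2, 2, k=3, stride=1, rng=np.random.default_rng(3)),
                (1, 5, 5, 2))


def test_batchnorm_input_gradient():
    _check_grad(BatchNorm2d(3), (2, 4, 4, 3))


def test_linear_input_gradient():
    layer = Linear(4, 2, rng=np.random.default_rng(4))
    x = RNG.normal(size=(3, 4)).astype(np.float32)
    r = RNG.normal(size=(3, 2)).astype(np.float32)
    layer.forward(x)
    analytic = layer.backward(r.copy())
    # input grad of x @ w + b has the closed form r @ w.T
    assert np.allclose(analytic, r @ layer.w.T, atol=1e-5)
    assert np.allclose(layer.gw, x.T @ r, atol=1e-5)


def test_batchnorm_train_normalizes_and_eval_uses_running_stats():
    bn = BatchNorm2d(2, momentum=1.0)  # running stats = last batch stats
    x = RNG.normal(3.0, 2.0, size=(4, 5, 5, 2)).astype(np.float32)
    y = bn.forward(x, train=True)
    assert np.allclose(y.mean(axis=(0, 1, 2)), 0.0, atol=1e-5)
    assert np.allclose(y.var(axis=(0, 1, 2)), 1.0, atol=1e-3)
    y_eval = bn.forward(x, train=False)
    assert np.allclose(y_eval, y, atol=1e-3)


def test_batchnorm_eval_backward_is_affine():
    bn = BatchNorm2d(2)
    bn.run_var[:] = [4.0, 0.25]
    x = RNG.normal(size=(1, 3, 3, 2)).astype(np.float32)
    bn.forward(x, train=False)
    g = np.ones((1, 3, 3, 2), dtype=np.float32)
    dx = bn.backward(g)
    expect = bn.gamma / np.sqrt(bn.run_var + bn.eps)
    assert np.allclose(dx, np.broadcast_to(expect, dx.shape), atol=1e-5)


def test_upsample_adjoint():
    up = Upsample2x()
    x = RNG.normal(size=(1, 3, 4, 2)).astype(np.float32)
    y = RNG.normal(size=(1, 6, 8, 2)).astype(np.float32)
    lhs = float((up.forward(x) * y).sum())
    rhs = float((x * up.backward(y)).sum())
    assert lhs == pytest.approx(rhs, rel=1e-5)


def test_relu():
    relu = ReLU()
    x = np.array([[-1.0, 2.0]], dtype=np.float32)
    assert np.array_equal(relu.forward(x), [[0.0, 2.0]])
    assert np.array_equal(relu.backward(np.ones_like(x)), [[0.0, 1.0]])


def test_softmax_and_sigmoid():
    z = RNG.normal(size=(2, 3, 5)).astype(np.float32)
    p = softmax(z)
    assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-6)
    assert sigmoid(np.array([0.0]))[0] == pytest.approx(0.5)
    assert sigmoid(np.array([800.0]))[0] == pytest.approx(1.0)  # no overflow


def test_bce_gradient_numeric():
    z = RNG.normal(size=6)
    y = (RNG.random(6) > 0.5).astype(float)
    _, grad = bce_with_logits(z, y)
    eps = 1e-6
    for i in range(6):
        zp, zm = z.copy(), z.copy()
        zp[i] += eps
        zm[i] -= eps
        num = (bce_with_logits(zp, y)[0] - bce_with_logits(zm, y)[0]) / (2 * eps)
        assert grad[i] == pytest.approx(num, rel=1e-3, abs=1e-7)


def test_dice_ce_gradient_numeric():
    logits = RNG.normal(size=(1, 4, 4, 4))
    targets = RNG.integers(0, 4, size=(1, 4, 4))
    _, grad = dice_ce_loss(logits, targets)
    eps = 1e-5
    rng = np.random.default_rng(5)
    for i in rng.choice(logits.size, size=10, replace=False):
        idx = np.unravel_index(i, logits.shape)
        lp, lm = logits.copy(), logits.copy()
        lp[idx] += eps
        lm[idx] -= eps
        num = (dice_ce_loss(lp, targets)[0] - dice_ce_loss(lm, targets)[0]) / (2 * eps)
        assert grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-6)


def test_dice_ce_perfect_prediction_low_loss():
    targets = np.zeros((1, 4, 4), dtype=int)
    targets[0, :2, :2] = 1
    logits = np.full((1, 4, 4, 4), -20.0)
    for c in range(4):
        logits[0, ..., c][targets[0] == c] = 20.0
    loss, _ = dice_ce_loss(logits, targets)
    assert loss < 1e-3


def test_classifier_learns_toy_task_and_is_deterministic():
    # bright top half vs bright bottom half
    rng = np.random.default_rng(6)
    x = rng.normal(0, 0.1, size=(40, 12, 12, 1)).astype(np.float32)
    y = np.arange(40) % 2
    x[y == 0, :6] += 1.0
    x[y == 1, 6:] += 1.0
    cfg = ClassifierConfig(epochs=4, width=4, batch_size=8, augment=False)
    m1 = fit_classifier(x, y, config=cfg, seed=1)
    m2 = fit_classifier(x, y, config=cfg, seed=1)
    assert m1.weights_hash() == m2.weights_hash()
    acc = ((m1.predict_proba(x) > 0.5) == y).mean()
    assert acc >= 0.9


def test_classifier_single_class_raises():
    x = np.zeros((4, 8, 8, 1), dtype=np.float32)
    with pytest.raises(ValueError):
        fit_classifier(x, np.zeros(4))


def test_segmenter_loss_decreases_and_shapes():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 0.05, size=(8, 16, 16, 1)).astype(np.float32)
    t = np.zeros((8, 16, 16), dtype=np.int64)
    t[:, 4:12, 4:12] = 1
    x[:, 4:12, 4:12] += 0.8
    cfg = SegmenterConfig(epochs=4, width=4, batch_size=4, augment=False)
    model, history = fit_segmenter(x, t, config=cfg, seed=1, return_history=True)
    assert history[-1] < history[0]
    pred = model.predict(x)
    assert pred.shape == (8, 16, 16) and pred.dtype == np.uint8
    z = model.encode(x)
    assert z.shape == (8, 16)  # 4 * width


def test_gradcam_head_input_grad_is_uniform():
    model = GroupClassifier(in_channels=1, width=4, seed=0)
    x = RNG.normal(size=(1, 8, 8, 1)).astype(np.float32)
    feats = model.forward_features(x, train=False)
    model.head(feats, train=False)
    da = model.head_input_grad(np.array([1.0], dtype=np.float32))
    model.zero_grads()
    # GAP head: gradient is spatially constant per channel
    assert np.allclose(da, da[:, :1, :1, :], atol=1e-7)
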