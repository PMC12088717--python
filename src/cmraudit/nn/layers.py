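"""Minimal CPU neural-network layers with hand-written backward passes.

Activations use NHWC layout (batch, row, col, channel) in float32 so every
convolution reduces to BLAS matrix multiplies over the trailing channel
axis.  Convolutions are evaluated as a sum over the k x k kernel offsets:
for each offset a strided slice of the padded input is multiplied with the
corresponding (cin, cout) weight slice.  This keeps both the forward and
backward passes allocation-light and fast enough to train the small
classifiers and segmenters used by the audit on a single CPU core.

Each layer caches what its backward pass needs during ``forward`` and
exposes ``params_grads()`` as a list of (parameter, gradient) pairs updated
in place by the optimizer.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

F32 = np.float32


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_grads(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        return []


class Conv2d(Layer):
    """k x k convolution, 'same' zero padding (k // 2), arbitrary stride."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: Optional[np.random.Generator] = None, bias: bool = True):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (k * k * cin))  # He initialization
        self.w = rng.normal(0.0, std, (k, k, cin, cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32) if bias else None
        self.k, self.stride = k, stride
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b) if bias else None

    def forward(self, x, train=True):
        k, s = self.k, self.stride
        p = k // 2
        n, h, w_, cin = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w_ + 2 * p - k) // s + 1
        cout = self.w.shape[-1]
        y = np.zeros((n * ho * wo, cout), dtype=F32)
        for i in range(k):
            for j in range(k):
                xs = xp[:, i:i + s * (ho - 1) + 1:s, j:j + s * (wo - 1) + 1:s, :]
                y += xs.reshape(-1, cin) @ self.w[i, j]
        if self.b is not None:
            y += self.b
        self._xp, self._shape = xp, (n, ho, wo)
        return y.reshape(n, ho, wo, cout)

    def backward(self, g):
        k, s = self.k, self.stride
        p = k // 2
        n, ho, wo = self._shape
        xp = self._xp
        cin = self.w.shape[2]
        gf = g.reshape(-1, self.w.shape[-1])
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = np.s_[:, i:i + s * (ho - 1) + 1:s, j:j + s * (wo - 1) + 1:s, :]
                xs = xp[sl].reshape(-1, cin)
                self.gw[i, j] += xs.T @ gf
                gxp[sl] += (gf @ self.w[i, j].T).reshape(n, ho, wo, cin)
        if self.b is not None:
            self.gb += gf.sum(axis=0)
        self._xp = None
        return gxp[:, p:xp.shape[1] - p, p:xp.shape[2] - p, :] if p else gxp

    def params_grads(self):
        pg = [(self.w, self.gw)]
        if self.b is not None:
            pg.append((self.b, self.gb))
        return pg


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.ggamma = np.zeros(c, dtype=F32)
        self.gbeta = np.zeros(c, dtype=F32)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean += self.momentum * (mu - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mu, var = self.run_mean, self.run_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, x.shape[0] * x.shape[1] * x.shape[2], train)
        return xhat * self.gamma + self.beta

    def backward(self, g):
        xhat, inv, m, trained = self._cache
        self.ggamma += (g * xhat).sum(axis=(0, 1, 2))
        self.gbeta += g.sum(axis=(0, 1, 2))
        dxhat = g * self.gamma
        if not trained:
            # eval mode normalizes with fixed running stats, so the layer is
            # a per-channel affine map and its input gradient has no
            # batch-statistics terms
            self._cache = None
            return (dxhat * inv).astype(F32)
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (inv / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx.astype(F32)

    def params_grads(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, g):
        out = np.where(self._mask, g, F32(0))
        self._mask = None
        return out


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, g):
        n, h, w, c = g.shape
        return g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._hw = x.shape[1] * x.shape[2]
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        n, h, w, c = self._shape
        return np.broadcast_to(
            g[:, None, None, :] / F32(self._hw), self._shape
        ).astype(F32)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / cin)
        self.w = rng.normal(0.0, std, (cin, cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.gw += self._x.T @ g
        self.gb += g.sum(axis=0)
        out = g @ self.w.T
        self._x = None
        return out

    def params_grads(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params_grads(self):
        return [pg for layer in self.layers for pg in layer.params_grads()]


# ---------------------------------------------------------------------------
# Losses (return loss value and gradient w.r.t. the logits)
# ---------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; targets in {0, 1}."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = ((sigmoid(z) - y) / z.size).astype(F32)
    return float(loss), grad


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def dice_ce_loss(
    logits: np.ndarray, targets: np.ndarray, n_classes: int = 4,
    dice_classes: Tuple[int, ...] = (1, 2, 3), eps: float = 1.0,
) -> Tuple[float, np.ndarray]:
    """Combined soft-Dice (foreground classes) + cross-entropy loss.

    ``logits``: (N, H, W, C); ``targets``: (N, H, W) integer labels.
    Returns (loss, dloss/dlogits).
    """
    p = softmax(logits.astype(np.float64))
    n, h, w, c = p.shape
    onehot = np.eye(c, dtype=np.float64)[targets]
    m = n * h * w

    ce = -np.log(np.clip((p * onehot).sum(-1), 1e-12, None)).mean()
    dldp = np.zeros_like(p)  # gradient w.r.t. probabilities (dice part)

    dice_terms = []
    for cls in dice_classes:
        pc, tc = p[..., cls], onehot[..., cls]
        inter = (pc * tc).sum()
        denom = pc.sum() + tc.sum() + eps
        d = (2.0 * inter + eps) / denom
        dice_terms.append(d)
        dldp[..., cls] += -(2.0 * tc - d) / denom / len(dice_classes)
    dice = float(np.mean(dice_terms))

    # chain dice gradient through the softmax, add the CE gradient
    dot = (dldp * p).sum(-1, keepdims=True)
    dz = p * (dldp - dot) + (p - onehot) / m
    loss = float(ce + (1.0 - dice))
    return loss, dz.astype(F32)
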