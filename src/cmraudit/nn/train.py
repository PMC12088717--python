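"""Training loops: SGD with momentum, learning-rate schedules, augmentation.

Two recipes are provided, mirroring common practice for each model family:

* classifier — binary cross-entropy, stepped learning-rate decay (factor 10
  at the schedule milestones), random mirroring and integer translation;
* segmenter — combined Dice + cross-entropy loss, 'poly' learning-rate
  decay ``lr0 * (1 - epoch/max_epochs)**0.9`` with Nesterov momentum,
  random integer translation applied jointly to image and label mask.

Defaults are scaled down (few epochs, small batches) for single-CPU runs;
full-scale settings are plain keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .layers import F32, bce_with_logits, dice_ce_loss
from .models import GroupClassifier, UNetSegmenter

__all__ = [
    "ClassifierConfig",
    "SegmenterConfig",
    "fit_classifier",
    "fit_segmenter",
]


@dataclass
class ClassifierConfig:
    epochs: int = 8
    lr: float = 0.02
    lr_decay_epochs: Tuple[int, ...] = ()  # e.g. (50,) for the full recipe
    momentum: float = 0.9
    batch_size: int = 16
    width: int = 8
    augment: bool = True
    max_shift: int = 4  # pixels of random translation
    mirror: bool = True


@dataclass
class SegmenterConfig:
    epochs: int = 10
    lr: float = 0.2
    momentum: float = 0.9
    nesterov: bool = True
    batch_size: int = 8
    width: int = 8
    augment: bool = True
    max_shift: int = 3
    mirror: bool = False  # mirroring swaps LV/RV laterality; off by default


class _SGD:
    def __init__(self, params_grads, lr, momentum, nesterov=False):
        self.pg = params_grads
        self.v = [np.zeros_like(p) for p, _ in params_grads]
        self.lr, self.mu, self.nesterov = lr, momentum, nesterov

    def step(self):
        for (p, g), v in zip(self.pg, self.v):
            v *= self.mu
            v -= self.lr * g
            if self.nesterov:
                p += self.mu * v - self.lr * g
            else:
                p += v
            g[...] = 0


def _translate(batch: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer translation with zero fill (NHWC or NHW)."""
    out = np.zeros_like(batch)
    h, w = batch.shape[1], batch.shape[2]
    rs, re = max(dr, 0), min(h + dr, h)
    cs, ce = max(dc, 0), min(w + dc, w)
    out[:, rs:re, cs:ce, ...] = batch[:, rs - dr:re - dr, cs - dc:ce - dc, ...]
    return out


def _augment_batch(xb, tb, rng, max_shift, mirror):
    if mirror and rng.random() < 0.5:
        xb = xb[:, :, ::-1]
        tb = tb[:, :, ::-1] if tb is not None and tb.ndim == 3 else tb
    if max_shift > 0:
        dr = int(rng.integers(-max_shift, max_shift + 1))
        dc = int(rng.integers(-max_shift, max_shift + 1))
        if dr or dc:
            xb = _translate(xb, dr, dc)
            if tb is not None and tb.ndim == 3:
                tb = _translate(tb, dr, dc)
    return np.ascontiguousarray(xb), tb


def fit_classifier(
    x: np.ndarray,
    y: np.ndarray,
    config: Optional[ClassifierConfig] = None,
    seed: int = 0,
    model: Optional[GroupClassifier] = None,
) -> GroupClassifier:
    """Train a binary group classifier on (N, H, W, C) inputs, labels {0,1}.

    Deterministic given ``seed`` (weight init, shuffling, augmentation).
    """
    cfg = config or ClassifierConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    if model is None:
        model = GroupClassifier(in_channels=x.shape[-1], width=cfg.width,
                                seed=int(rng.integers(2 ** 31)))
    opt = _SGD(model.params_grads(), cfg.lr, cfg.momentum)
    x = x.astype(F32)
    n = len(x)
    for epoch in range(cfg.epochs):
        if cfg.lr_decay_epochs:
            k = sum(epoch >= e for e in cfg.lr_decay_epochs)
            opt.lr = cfg.lr * (0.1 ** k)
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            if cfg.augment:
                xb, _ = _augment_batch(xb, None, rng, cfg.max_shift, cfg.mirror)
            logits = model.forward(xb, train=True)
            _, dz = bce_with_logits(logits, yb)
            model.backward(dz)
            opt.step()
    return model


def fit_segmenter(
    x: np.ndarray,
    t: np.ndarray,
    config: Optional[SegmenterConfig] = None,
    seed: int = 0,
    model: Optional[UNetSegmenter] = None,
    return_history: bool = False,
):
    """Train a 4-class segmenter on (N, H, W, 1) images and (N, H, W) label
    masks with Dice + cross-entropy loss and poly learning-rate decay."""
    cfg = config or SegmenterConfig()
    if len(x) < 1:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    if model is None:
        model = UNetSegmenter(in_channels=x.shape[-1], width=cfg.width,
                              seed=int(rng.integers(2 ** 31)))
    opt = _SGD(model.params_grads(), cfg.lr, cfg.momentum, cfg.nesterov)
    x = x.astype(F32)
    t = t.astype(np.int64)
    n = len(x)
    history = []
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * (1.0 - epoch / cfg.epochs) ** 0.9
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, tb = x[idx], t[idx]
            if cfg.augment:
                xb, tb = _augment_batch(xb, tb, rng, cfg.max_shift, cfg.mirror)
            logits = model.forward(xb, train=True)
            loss, dz = dice_ce_loss(logits, tb, n_classes=model.n_classes)
            model.backward(dz)
            opt.step()
            epoch_loss += loss
            nb += 1
        history.append(epoch_loss / max(nb, 1))
    if return_history:
        return model, history
    return model
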