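"""Network architectures for the audit: a reduced residual CNN classifier
and a small U-shaped encoder-decoder segmenter.

Both are deliberately narrow (default base width 8) so that training on a
single CPU core is fast; the training recipes (SGD with momentum, stepped or
poly learning-rate decay, Dice + cross-entropy loss) follow standard
practice for this class of model.
"""

from __future__ import annotations

import hashlib
from typing import List, Optional, Tuple

import numpy as np

from .layers import (
    F32,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    ReLU,
    Sequential,
    Upsample2x,
)

__all__ = ["ResidualBlock", "GroupClassifier", "UNetSegmenter"]


def conv_bn_relu(cin, cout, rng, stride=1, k=3) -> Sequential:
    return Sequential(Conv2d(cin, cout, k=k, stride=stride, rng=rng),
                      BatchNorm2d(cout), ReLU())


class ResidualBlock(Layer):
    """conv-bn-relu-conv-bn plus identity (or 1x1 projection) skip, final ReLU."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.main = Sequential(
            Conv2d(cin, cout, 3, stride, rng), BatchNorm2d(cout), ReLU(),
            Conv2d(cout, cout, 3, 1, rng), BatchNorm2d(cout),
        )
        if stride != 1 or cin != cout:
            self.skip = Sequential(Conv2d(cin, cout, 1, stride, rng), BatchNorm2d(cout))
        else:
            self.skip = None
        self.relu = ReLU()

    def forward(self, x, train=True):
        y = self.main.forward(x, train)
        s = self.skip.forward(x, train) if self.skip is not None else x
        return self.relu.forward(y + s, train)

    def backward(self, g):
        g = self.relu.backward(g)
        gx = self.main.backward(g)
        if self.skip is not None:
            gx = gx + self.skip.backward(g)
        else:
            gx = gx + g
        return gx

    def params_grads(self):
        pg = self.main.params_grads()
        if self.skip is not None:
            pg += self.skip.params_grads()
        return pg


class _ModelBase:
    def params_grads(self):
        raise NotImplementedError

    def zero_grads(self):
        for _, g in self.params_grads():
            g[...] = 0

    def weights_hash(self) -> str:
        """Hash of all parameters; equal hashes mean identical weights."""
        h = hashlib.sha256()
        for p, _ in self.params_grads():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()


class GroupClassifier(_ModelBase):
    """Reduced residual CNN for binary protected-group classification.

    stem conv -> two stride-2 residual stages -> global average pool ->
    linear logit.  The output of the last residual stage (post-ReLU) is the
    "last convolutional layer" activation used by GradCAM.
    """

    def __init__(self, in_channels: int = 3, width: int = 8,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.features = Sequential(
            conv_bn_relu(in_channels, width, rng),
            ResidualBlock(width, 2 * width, 2, rng),
            ResidualBlock(2 * width, 4 * width, 2, rng),
        )
        self.pool = GlobalAvgPool()
        self.fc = Linear(4 * width, 1, rng)
        self.width = width

    def forward_features(self, x, train=True):
        return self.features.forward(x.astype(F32), train)

    def head(self, feats, train=True):
        return self.fc.forward(self.pool.forward(feats, train), train)[:, 0]

    def forward(self, x, train=True):
        return self.head(self.forward_features(x, train), train)

    def backward(self, dlogits):
        g = self.fc.backward(dlogits[:, None].astype(F32))
        g = self.pool.backward(g)
        return self.features.backward(g)

    def head_input_grad(self, dlogits):
        """Gradient of the logits w.r.t. the feature maps, through the head
        only (used by GradCAM).  Accumulates head parameter grads too; call
        ``zero_grads`` afterwards when used outside training."""
        g = self.fc.backward(dlogits[:, None].astype(F32))
        return self.pool.backward(g)

    def predict_proba(self, x, batch: int = 64) -> np.ndarray:
        from .layers import sigmoid

        out = []
        for i in range(0, len(x), batch):
            out.append(sigmoid(self.forward(x[i:i + batch], train=False)))
        return np.concatenate(out)

    def params_grads(self):
        return (self.features.params_grads() + self.fc.params_grads())


class UNetSegmenter(_ModelBase):
    """Small U-shaped encoder-decoder for 4-class cardiac segmentation.

    Encoder: width w at full resolution, 2w at /2, 4w at /4 (bottleneck).
    Decoder: nearest upsampling + convolution with skip concatenation.
    ``encode`` exposes the spatially pooled bottleneck as the latent vector
    used for demographic probing.
    """

    def __init__(self, in_channels: int = 1, width: int = 8, n_classes: int = 4,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        w = width
        self.enc0 = Sequential(conv_bn_relu(in_channels, w, rng),
                               conv_bn_relu(w, w, rng))
        self.enc1 = Sequential(conv_bn_relu(w, 2 * w, rng, stride=2),
                               conv_bn_relu(2 * w, 2 * w, rng))
        self.enc2 = Sequential(conv_bn_relu(2 * w, 4 * w, rng, stride=2),
                               conv_bn_relu(4 * w, 4 * w, rng))
        self.up1 = Sequential(Upsample2x(), conv_bn_relu(4 * w, 2 * w, rng))
        self.dec1 = conv_bn_relu(4 * w, 2 * w, rng)
        self.up2 = Sequential(Upsample2x(), conv_bn_relu(2 * w, w, rng))
        self.dec2 = conv_bn_relu(2 * w, w, rng)
        self.out = Conv2d(w, n_classes, k=1, stride=1, rng=rng)
        self.width = w
        self.n_classes = n_classes

    # -- forward ----------------------------------------------------------
    def forward(self, x, train=True):
        x = x.astype(F32)
        e0 = self.enc0.forward(x, train)
        e1 = self.enc1.forward(e0, train)
        e2 = self.enc2.forward(e1, train)
        u1 = self.up1.forward(e2, train)
        d1 = self.dec1.forward(np.concatenate([u1, e1], axis=-1), train)
        u2 = self.up2.forward(d1, train)
        d2 = self.dec2.forward(np.concatenate([u2, e0], axis=-1), train)
        self._w2 = (u1.shape[-1], u2.shape[-1])
        return self.out.forward(d2, train)

    def backward(self, dlogits):
        c1, c2 = self._w2
        g = self.out.backward(dlogits.astype(F32))
        g = self.dec2.backward(g)
        gu2, ge0_skip = g[..., :c2], g[..., c2:]
        g = self.up2.backward(gu2)
        g = self.dec1.backward(g)
        gu1, ge1_skip = g[..., :c1], g[..., c1:]
        g = self.up1.backward(gu1)
        g = self.enc2.backward(g)
        g = self.enc1.backward(g + ge1_skip)
        return self.enc0.backward(g + ge0_skip)

    # -- inference --------------------------------------------------------
    def predict_logits(self, x, batch: int = 32) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch):
            out.append(self.forward(x[i:i + batch], train=False))
        return np.concatenate(out)

    def predict(self, x, batch: int = 32) -> np.ndarray:
        """Per-pixel argmax labels, (N, H, W) uint8."""
        return self.predict_logits(x, batch).argmax(axis=-1).astype(np.uint8)

    def encode(self, x, batch: int = 32) -> np.ndarray:
        """Bottleneck feature maps average-pooled to one vector per image."""
        out = []
        x = x.astype(F32)
        for i in range(0, len(x), batch):
            xb = x[i:i + batch]
            e0 = self.enc0.forward(xb, train=False)
            e1 = self.enc1.forward(e0, train=False)
            e2 = self.enc2.forward(e1, train=False)
            out.append(e2.mean(axis=(1, 2)))
        return np.concatenate(out)

    def params_grads(self):
        parts = [self.enc0, self.enc1, self.enc2, self.up1, self.dec1,
                 self.up2, self.dec2, self.out]
        return [pg for p in parts for pg in p.params_grads()]
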