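"""GradCAM attribution and the peak-region taxonomy."""

import numpy as np
import pytest

from cmraudit import saliency
from cmraudit.nn.layers import GlobalAvgPool, Layer, Linear, Sequential
from cmraudit.saliency import (
    AttributionMap,
    RegionTaxonomy,
    gradcam_map,
    peak_region_label,
    region_attribution_summary,
    subject_region_masks,
)


class _Identity(Layer):
    def forward(self, x, train=True):
        return x

    def backward(self, g):
        return g


class _ToyModel:
    """One 'convolutional layer' that is the input itself, GAP + linear head."""

    def __init__(self, w):
        self.features = Sequential(_Identity())
        self.pool = GlobalAvgPool()
        self.fc = Linear(len(w), 1, rng=np.random.default_rng(0))
        self.fc.w[:] = np.asarray(w, dtype=np.float32)[:, None]
        self.fc.b[:] = 0.0

    def head(self, feats, train=True):
        return self.fc.forward(self.pool.forward(feats, train), train)[:, 0]

    def head_input_grad(self, d):
        g = self.fc.backward(d[:, None].astype(np.float32))
        return self.pool.backward(g)

    def zero_grads(self):
        self.fc.gw[...] = 0
        self.fc.gb[...] = 0


def test_gradcam_toy_closed_form():
    # cam = ReLU(sum_c w_c * A_c) / max, since GAP-head gradients are uniform
    w = [1.0, -2.0, 0.5]
    model = _ToyModel(w)
    rng = np.random.default_rng(1)
    a = rng.normal(size=(5, 6, 3)).astype(np.float32)
    cam = gradcam_map(model, a, target_class=1).heatmap
    raw = np.maximum((a * np.array(w, dtype=np.float32)).sum(axis=-1), 0.0)
    expect = raw / raw.max()
    assert np.abs(cam - expect).max() < 1e-6


def test_gradcam_target_class_zero_flips_sign():
    model = _ToyModel([1.0])
    a = np.array([[[1.0], [-1.0]]], dtype=np.float32)
    cam1 = gradcam_map(model, a, target_class=1).heatmap
    cam0 = gradcam_map(model, a, target_class=0).heatmap
    assert cam1[0, 0] == 1.0 and cam1[0, 1] == 0.0
    assert cam0[0, 0] == 0.0 and cam0[0, 1] == 1.0


def test_gradcam_all_negative_map_is_zero():
    model = _ToyModel([-1.0])
    a = np.ones((2, 2, 1), dtype=np.float32)
    cam = gradcam_map(model, a).heatmap
    assert np.all(cam == 0.0)


def test_gradcam_on_real_model_shapes(tiny_classifier):
    x = np.random.default_rng(0).random((48, 48, 3)).astype(np.float32)
    for layer in (0, 1, -1):
        amap = gradcam_map(tiny_classifier, x, layer=layer)
        assert amap.heatmap.shape == (48, 48)
        assert amap.heatmap.min() >= 0.0
        assert amap.heatmap.max() == pytest.approx(1.0)
    assert gradcam_map(tiny_classifier, x, layer=0).layer == "features[0]"


def test_attribution_map_rejects_negative():
    with pytest.raises(ValueError):
        AttributionMap(heatmap=np.array([[-0.1]]))


def _masks():
    heart = np.zeros((4, 4), dtype=bool)
    body = np.zeros((4, 4), dtype=bool)
    ghost = np.zeros((4, 4), dtype=bool)
    heart[1, 1] = True
    body[2, 2] = True
    ghost[3, 3] = True
    return heart, body, ghost


def test_peak_region_label_precedence():
    heart, body, ghost = _masks()
    hm = np.zeros((4, 4))
    hm[3, 3] = 1.0
    heart_here = heart.copy()
    heart_here[3, 3] = True  # overlap: artefact takes precedence
    amap = AttributionMap(heatmap=hm)
    assert peak_region_label(amap, heart_here, body, ghost) == "artefact"
    assert peak_region_label(amap, heart_here, body, np.zeros_like(ghost)) == "heart"
    hm2 = np.zeros((4, 4))
    hm2[0, 0] = 1.0
    assert peak_region_label(AttributionMap(heatmap=hm2), heart, body, ghost) == "other"
    assert peak_region_label(AttributionMap(heatmap=np.zeros((4, 4))),
                             heart, body, ghost) == "other"


def test_peak_region_label_mass_criterion():
    heart, body, ghost = _masks()
    hm = np.zeros((4, 4))
    hm[1, 1] = 0.6  # 60% of mass on the heart
    hm[0, 0] = 0.4
    amap = AttributionMap(heatmap=hm)
    assert peak_region_label(amap, heart, body, ghost, criterion="mass") == "heart"
    assert peak_region_label(amap, heart, body, ghost, criterion="mass",
                             mass_threshold=0.7) == "other"
    with pytest.raises(ValueError):
        peak_region_label(amap, heart, body, ghost, criterion="bogus")


def test_region_taxonomy_fractions():
    tax = RegionTaxonomy.from_labels(["heart", "heart", "artefact", "other"])
    assert tax.fractions["heart"] == 0.5
    assert tax.fractions["artefact"] == 0.25
    assert sum(tax.fractions.values()) == pytest.approx(1.0)


def test_subject_region_masks(subject):
    m = subject_region_masks(subject, "ED", downsample=2)
    assert m["heart"].shape == (48, 48)
    assert not (m["heart"] & m["body"]).any()
    if subject.meta["has_ghost"]:
        assert m["ghost"].any()
    undilated = subject_region_masks(subject, "ED", downsample=2, dilation=0)
    assert m["body"].sum() >= undilated["body"].sum()


def test_region_attribution_summary_empty_raises(tiny_classifier):
    with pytest.raises(ValueError):
        region_attribution_summary(tiny_classifier, np.zeros((0, 8, 8, 3)), [])


def test_cohort_attribution_summary(tiny_classifier, small_cohort):
    tax = saliency.cohort_attribution_summary(
        tiny_classifier, small_cohort.subjects[:2], layer=0
    )
    assert len(tax.labels) == 4  # two subjects x two frames
    assert sum(tax.fractions.values()) == pytest.approx(1.0)
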