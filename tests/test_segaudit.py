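"""Dice, Mann-Whitney, sweep plumbing."""

import numpy as np
import pytest
from scipy import stats

from cmraudit import segaudit
from cmraudit.design import ImbalanceSplit
from cmraudit.nn import SegmenterConfig
from cmraudit.segaudit import (
    SweepResult,
    _pad_to_multiple,
    dice,
    mann_whitney,
    per_group_dsc,
    predict_mask,
    run_imbalance_sweep,
    significance_stars,
    subject_dsc,
    subjects_to_arrays,
)


def _brute_dice(pred, gt, label):
    p = {tuple(i) for i in np.argwhere(pred == label)}
    g = {tuple(i) for i in np.argwhere(gt == label)}
    if not p and not g:
        return 1.0
    return 2 * len(p & g) / (len(p) + len(g))


def test_dice_matches_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(30):
        a = rng.integers(0, 4, size=(9, 7)).astype(np.uint8)
        b = rng.integers(0, 4, size=(9, 7)).astype(np.uint8)
        for label in (0, 1, 2, 3):
            assert dice(a, b, label) == pytest.approx(_brute_dice(a, b, label))


def test_dice_edge_cases():
    z = np.zeros((3, 3), dtype=np.uint8)
    assert dice(z, z, 1) == 1.0  # absent from both
    o = np.ones((3, 3), dtype=np.uint8)
    assert dice(o, o, 1) == 1.0
    assert dice(o, z, 1) == 0.0
    with pytest.raises(ValueError):
        dice(np.zeros((2, 2)), np.zeros((3, 3)), 1)


def test_pad_to_multiple():
    assert _pad_to_multiple(np.ones((6, 7)), 4).shape == (8, 8)
    assert _pad_to_multiple(np.ones((8, 8)), 4).shape == (8, 8)
    padded = _pad_to_multiple(np.ones((6, 6)), 4)
    assert padded[6:].sum() == 0  # trailing zero pad


def test_subjects_to_arrays(small_cohort):
    x, t, ids = subjects_to_arrays(small_cohort.subjects[:3], downsample=2)
    assert x.shape == (6, 48, 48, 1)
    assert t.shape == (6, 48, 48)
    assert x.min() >= 0.0 and x.max() <= 1.0
    assert len(ids) == 6


def test_mann_whitney_exact_and_asymptotic():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    b = [6.0, 7.0, 8.0, 9.0, 10.0]
    assert mann_whitney(a, b) == pytest.approx(2 / 252)
    big_a = list(np.random.default_rng(0).normal(size=30))
    big_b = list(np.random.default_rng(1).normal(size=30))
    expect = stats.mannwhitneyu(big_a, big_b, alternative="two-sided",
                                method="asymptotic").pvalue
    assert mann_whitney(big_a, big_b) == pytest.approx(float(expect))
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_significance_stars():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(1e-5) == "****"


def test_sweep_result_median_gap_and_summary():
    res = SweepResult(
        intervention="original",
        fractions=[0.5],
        dsc={0.5: {"A": [0.9, 0.8, 0.7], "B": [0.6, 0.5, 0.4]}},
        p_values={0.5: 0.03},
        test_ids=["x"],
    )
    assert res.median_gap(0.5) == pytest.approx(0.3)
    row = res.summary().iloc[0]
    assert row["median_dsc_a"] == 0.8 and row["stars"] == "*"


def test_predict_and_subject_dsc(tiny_segmenter, subject):
    x, t, _ = subjects_to_arrays([subject])
    pred = predict_mask(tiny_segmenter, x[0])
    assert pred.shape == t[0].shape
    d = subject_dsc(tiny_segmenter, subject)
    assert 0.0 <= d <= 1.0
    dp = subject_dsc(tiny_segmenter, subject, pooled=True)
    assert 0.0 <= dp <= 1.0


def test_per_group_dsc(tiny_segmenter, small_cohort):
    subs = small_cohort.subjects[:2] + small_cohort.subjects[6:8]
    out = per_group_dsc(tiny_segmenter, subs)
    assert len(out["A"]) == 2 and len(out["B"]) == 2
    assert all(0.0 <= v <= 1.0 for g in out.values() for v in g)


def test_run_imbalance_sweep_smoke(small_cohort):
    by_id = {s.subject_id: s for s in small_cohort.subjects}
    ids_a = [s.subject_id for s in small_cohort.by_group("A")]
    ids_b = [s.subject_id for s in small_cohort.by_group("B")]
    splits = [
        ImbalanceSplit(0.0, train_a=ids_a[:4], train_b=[]),
        ImbalanceSplit(1.0, train_a=[], train_b=ids_b[:4]),
    ]
    test_ids = ids_a[4:] + ids_b[4:]
    cfg = SegmenterConfig(epochs=1, width=4, batch_size=4)
    res = run_imbalance_sweep(by_id, splits, test_ids, seed=0, config=cfg)
    assert res.fractions == [0.0, 1.0]
    assert set(res.dsc[0.0]) == {"A", "B"}
    assert all(0.0 <= p <= 1.0 for p in res.p_values.values())
    with pytest.raises(ValueError):
        run_imbalance_sweep(by_id, splits, test_ids, intervention="bogus")


def test_sweep_cropped_uses_training_pool_window(small_cohort):
    by_id = {s.subject_id: s for s in small_cohort.subjects}
    ids_a = [s.subject_id for s in small_cohort.by_group("A")]
    ids_b = [s.subject_id for s in small_cohort.by_group("B")]
    splits = [ImbalanceSplit(0.5, train_a=ids_a[:2], train_b=ids_b[:2])]
    test_ids = ids_a[4:] + ids_b[4:]
    cfg = SegmenterConfig(epochs=1, width=4, batch_size=4)
    res = run_imbalance_sweep(by_id, splits, test_ids, intervention="cropped",
                              seed=0, config=cfg)
    assert res.intervention == "cropped"
    assert 0.0 <= res.p_values[0.5] <= 1.0
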