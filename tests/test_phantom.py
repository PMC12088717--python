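"""Generator: geometry, shifts, ghosting oracle, reproducibility."""

import numpy as np
import pytest

from cmraudit.phantom import (
    CovariateRecord,
    PhantomGeometry,
    ShiftConfig,
    default_covariate_params,
    generate_cohort,
    inject_ghosting,
    null_covariate_params,
    render_subject,
    sample_covariates,
)


def test_cohort_shapes_and_dtypes(small_cohort):
    assert len(small_cohort) == 12
    for s in small_cohort.subjects:
        for fr in ("ED", "ES"):
            assert s.frames[fr].shape == (96, 96)
            assert s.frames[fr].dtype == np.float32
            assert s.masks[fr].shape == (96, 96)
            assert s.masks[fr].dtype == np.uint8
            assert set(np.unique(s.masks[fr])) <= {0, 1, 2, 3}
        assert set(s.aux) == {"body", "fat_ring", "ghost"}


def test_reproducibility():
    a = generate_cohort(3, ShiftConfig(), seed=5)
    b = generate_cohort(3, ShiftConfig(), seed=5)
    c = generate_cohort(3, ShiftConfig(), seed=6)
    for sa, sb in zip(a.subjects, b.subjects):
        assert np.array_equal(sa.frames["ED"], sb.frames["ED"])
        assert sa.covariates.as_dict() == sb.covariates.as_dict()
    assert not np.array_equal(a.subjects[0].frames["ED"], c.subjects[0].frames["ED"])


def test_sex_balance():
    coh = generate_cohort(7, ShiftConfig(), seed=1)
    for g in ("A", "B"):
        sexes = [s.covariates.sex for s in coh.by_group(g)]
        assert sexes.count("M") == 4 and sexes.count("F") == 3


def test_null_shift_group_exchangeable():
    # identical covariates, different group label, same rng state -> same image
    params = null_covariate_params()
    cov_a = sample_covariates("A", params, np.random.default_rng(3),
                              subject_id="x", sex="M")
    cov_b = CovariateRecord(**{**cov_a.as_dict(), "group": "B"})
    sa = render_subject(cov_a, ShiftConfig.null(), np.random.default_rng(9),
                        params=params)
    sb = render_subject(cov_b, ShiftConfig.null(), np.random.default_rng(9),
                        params=params)
    assert np.array_equal(sa.frames["ED"], sb.frames["ED"])
    assert np.array_equal(sa.masks["ES"], sb.masks["ES"])


def test_fat_shift_raises_group_b_thickness(small_cohort):
    mean = {
        g: np.mean([s.meta["fat_thickness"] for s in small_cohort.by_group(g)])
        for g in ("A", "B")
    }
    assert mean["B"] > mean["A"] + 1.0  # delta is 2.5 px


def test_masks_unaffected_by_image_shifts():
    cov = sample_covariates("B", rng=np.random.default_rng(0), subject_id="x")
    shifted = render_subject(cov, ShiftConfig(), np.random.default_rng(1))
    null = render_subject(cov, ShiftConfig.null(), np.random.default_rng(1))
    for fr in ("ED", "ES"):
        assert np.array_equal(shifted.masks[fr], null.masks[fr])


def test_inject_ghosting_oracle():
    img = np.zeros((10, 4), dtype=np.float32)
    ring = np.zeros((10, 4), dtype=bool)
    img[1, :] = 0.8
    ring[1, :] = True
    out, support = inject_ghosting(img, ring, amplitude=0.5, spacing=3, n_echoes=2)
    expect = img.copy()
    expect[4, :] += 0.5 * 0.8   # echo 1 at row 1+3
    expect[7, :] += 0.25 * 0.8  # echo 2 at row 1+6
    assert np.allclose(out, expect)
    assert support[4].all() and support[7].all()
    assert support.sum() == 8


def test_inject_ghosting_clipping_and_zero_amplitude():
    img = np.ones((5, 2), dtype=np.float32)
    ring = np.ones((5, 2), dtype=bool)
    out, support = inject_ghosting(img, ring, amplitude=0.4, spacing=7, n_echoes=3)
    assert np.array_equal(out, img) and not support.any()
    out, support = inject_ghosting(img, ring, amplitude=0.0, spacing=1, n_echoes=3)
    assert np.array_equal(out, img) and not support.any()
    with pytest.raises(ValueError):
        inject_ghosting(img, ring, amplitude=0.4, spacing=0, n_echoes=1)


def test_ghost_prevalence_extremes():
    always = ShiftConfig(ghost_prevalence={"A": 1.0, "B": 1.0})
    never = ShiftConfig(ghost_prevalence={"A": 0.0, "B": 0.0})
    ca = generate_cohort(4, always, seed=2)
    cn = generate_cohort(4, never, seed=2)
    assert all(s.meta["has_ghost"] for s in ca.subjects)
    assert not any(s.meta["has_ghost"] for s in cn.subjects)


def test_aux_masks_disjoint_from_heart(small_cohort):
    for s in small_cohort.subjects:
        heart = (s.masks["ED"] > 0) | (s.masks["ES"] > 0)
        assert not (s.aux["fat_ring"] & heart).any()
        assert not (s.aux["ghost"] & heart).any()


def test_covariate_record_validation():
    rec = sample_covariates("A", rng=np.random.default_rng(0))
    rec.validate()  # internally consistent by construction
    bad = CovariateRecord(**{**rec.as_dict(), "group": "C"})
    with pytest.raises(ValueError):
        bad.validate()
    inconsistent = CovariateRecord(**{**rec.as_dict(), "weight": rec.weight + 50})
    with pytest.raises(ValueError):
        inconsistent.validate()


def test_shift_config_null_and_validation():
    assert ShiftConfig.null().is_null
    assert not ShiftConfig().is_null
    # equal nonzero prevalences are still exchangeable
    assert ShiftConfig(
        fat_thickness_delta=0, fat_intensity_delta=0,
        ghost_prevalence={"A": 0.3, "B": 0.3},
    ).is_null
    with pytest.raises(ValueError):
        ShiftConfig(ghost_prevalence={"A": 1.5, "B": 0.0}).validate()
    with pytest.raises(ValueError):
        ShiftConfig(noise_sigma=-1).validate()


def test_bmi_fat_coupling_within_group():
    params = default_covariate_params()
    rng = np.random.default_rng(0)
    recs = [sample_covariates("A", params, rng, subject_id=f"s{i}")
            for i in range(12)]
    subs = [render_subject(r, ShiftConfig(), np.random.default_rng(1)) for r in recs]
    bmi = np.array([r.bmi for r in recs])
    fat = np.array([s.meta["fat_thickness"] for s in subs])
    assert np.corrcoef(bmi, fat)[0, 1] > 0.9


def test_geometry_bounds_error():
    geom = PhantomGeometry(lv_center=(90.0, 42.0))
    cov = sample_covariates("A", rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        render_subject(cov, ShiftConfig(), np.random.default_rng(0), geometry=geom)
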