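"""Shared fixtures: one small shifted cohort and tiny trained models.

Session scope keeps the suite fast — the cohort and the two trained
networks are built once and reused read-only across test modules.
"""

import numpy as np
import pytest

from cmraudit import channels, segaudit
from cmraudit.nn import ClassifierConfig, SegmenterConfig
from cmraudit.phantom import ShiftConfig, generate_cohort

TINY_CLS = ClassifierConfig(epochs=2, batch_size=8, width=4)
TINY_SEG = SegmenterConfig(epochs=2, batch_size=4, width=4)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(6, ShiftConfig(), seed=123)


@pytest.fixture(scope="session")
def null_cohort():
    from cmraudit.phantom import null_covariate_params

    return generate_cohort(
        6, ShiftConfig.null(), seed=124, params=null_covariate_params()
    )


@pytest.fixture(scope="session")
def subject(small_cohort):
    return small_cohort.subjects[0]


@pytest.fixture(scope="session")
def tiny_classifier(small_cohort):
    x, y, _ = channels.build_dataset(small_cohort.subjects, "iii", 2)
    return channels.train_group_classifier(x, y, config=TINY_CLS, seed=7)


@pytest.fixture(scope="session")
def tiny_segmenter(small_cohort):
    train = small_cohort.subjects[:3] + small_cohort.subjects[6:9]
    return segaudit.train_segmenter(train, config=TINY_SEG, seed=7)
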