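"""Latent-space demographic probing of trained segmentation encoders.

A segmenter's decoder is discarded; the held-out test images are pushed
through the encoder and the bottleneck feature maps are average-pooled into
one vector per image.  PCA reduces the vectors, and a logistic-regression
probe estimates (by stratified cross-validation) how accurately the
protected group can be read off the representation.  Probe accuracy well
above chance for encoders trained at every imbalance level — including
single-group training sets — demonstrates that the group shift is encoded
in the model whether or not the minority group was seen in training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .nn import UNetSegmenter
from .segaudit import subjects_to_arrays
from .phantom import PhantomSubject

__all__ = ["extract_latent", "extract_cohort_latents", "pca_reduce", "probe_accuracy"]


def extract_latent(model: UNetSegmenter, image: np.ndarray) -> np.ndarray:
    """Spatially averaged bottleneck features for one normalized image."""
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[..., None]
    return model.encode(x[None])[0]


def extract_cohort_latents(
    model: UNetSegmenter,
    subjects: Sequence[PhantomSubject],
    downsample: int = 2,
) -> Tuple[np.ndarray, np.ndarray]:
    """(latents, group labels) with one row per frame of each subject."""
    x, _, _ = subjects_to_arrays(subjects, downsample)
    z = model.encode(x)
    y = np.array([1 if s.group == "B" else 0 for s in subjects for _ in ("ED", "ES")])
    return z, y


def pca_reduce(
    vectors: np.ndarray, n_components: int = 10
) -> Tuple[np.ndarray, np.ndarray]:
    """Centred projection onto the top principal components.

    Returns (reduced vectors, explained-variance ratios, non-increasing).
    """
    n, d = vectors.shape
    if n_components > min(n, d):
        raise ValueError("n_components exceeds min(n_samples, dim)")
    pca = PCA(n_components=n_components, svd_solver="full")
    reduced = pca.fit_transform(vectors)
    return reduced, pca.explained_variance_ratio_


def probe_accuracy(
    reduced: np.ndarray,
    labels: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified cross-validated logistic-regression accuracy."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("probe needs both classes present")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    clf = LogisticRegression(max_iter=2000)
    scores = cross_val_score(clf, reduced, labels, cv=cv, scoring="accuracy")
    return float(scores.mean())
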