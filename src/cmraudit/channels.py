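"""Group-separability audit: classify protected group from images and/or
segmentations.

The central design packs three greyscale channels per sample, each either a
min-max-normalized CMR image (Im) or an intensity-encoded ground-truth
segmentation (Seg), giving four combinations (Im-Im-Im, Im-Im-Seg,
Im-Seg-Seg, Seg-Seg-Seg).  Comparing classification accuracy across the
combinations quantifies how much of the between-group distributional shift
lives in the images versus the segmentations: if segmentations carry no
group signal, Seg-Seg-Seg accuracy sits at chance while Im-Im-Im tracks the
image-borne shift.

Each configuration is trained repeatedly (default 10 runs) with different
seeds and train/validation subsamples; accuracy, sensitivity, and
specificity (group B positive) are reported as mean (SD) over runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .nn import ClassifierConfig, GroupClassifier, fit_classifier
from .phantom import Cohort, PhantomSubject

__all__ = [
    "COMBOS",
    "canonical_combo",
    "AuditSummary",
    "normalize_image",
    "encode_mask_channel",
    "compose_channels",
    "downsample_image",
    "downsample_mask",
    "build_dataset",
    "train_group_classifier",
    "evaluate_classifier",
    "repeat_audit",
    "compare_audits_ttest",
    "mean_intensity_histogram",
]

#: the four channel combinations, as (short key, display name)
COMBOS = {
    "iii": "Im-Im-Im",
    "iis": "Im-Im-Seg",
    "iss": "Im-Seg-Seg",
    "sss": "Seg-Seg-Seg",
}

_N_LABELS = 4


def canonical_combo(combo: str) -> str:
    """Normalize 'Im-Im-Seg' / 'iis' style spellings to the short key."""
    c = combo.strip().lower().replace("im", "i").replace("seg", "s").replace("-", "")
    if c not in COMBOS:
        raise ValueError(f"unknown channel combination {combo!r}")
    return c


@dataclass
class AuditSummary:
    """Mean (SD) accuracy/sensitivity/specificity over repeated runs."""

    combo: str
    accuracy: np.ndarray  # per-run values
    sensitivity: np.ndarray
    specificity: np.ndarray

    def _ms(self, a) -> Tuple[float, float]:
        return float(np.mean(a)), float(np.std(a, ddof=1)) if len(a) > 1 else 0.0

    @property
    def accuracy_mean(self):
        return float(np.mean(self.accuracy))

    @property
    def accuracy_sd(self):
        return float(np.std(self.accuracy, ddof=1)) if len(self.accuracy) > 1 else 0.0

    def as_dict(self) -> Dict[str, float]:
        def ms(a):
            sd = float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
            return float(np.mean(a)), sd

        acc, acc_sd = ms(self.accuracy)
        sen, sen_sd = ms(self.sensitivity)
        spe, spe_sd = ms(self.specificity)
        return {
            "combo": COMBOS[self.combo],
            "n_runs": len(self.accuracy),
            "accuracy_mean": acc,
            "accuracy_sd": acc_sd,
            "sensitivity_mean": sen,
            "sensitivity_sd": sen_sd,
            "specificity_mean": spe,
            "specificity_sd": spe_sd,
        }


# ---------------------------------------------------------------------------
# Channel construction
# ---------------------------------------------------------------------------

def normalize_image(image: np.ndarray) -> np.ndarray:
    """Min-max scale an image to [0, 1]; a constant image is degenerate."""
    lo, hi = float(image.min()), float(image.max())
    if hi - lo <= 0:
        raise ValueError("constant image cannot be min-max normalized")
    return ((image - lo) / (hi - lo)).astype(np.float32)


def encode_mask_channel(mask: np.ndarray) -> np.ndarray:
    """Map labels {0,1,2,3} to equispaced intensities {0, 1/3, 2/3, 1}."""
    m = np.asarray(mask)
    if m.size and (m.min() < 0 or m.max() > _N_LABELS - 1):
        raise ValueError("mask contains unknown label codes")
    return (m.astype(np.float32)) / (_N_LABELS - 1)


def decode_mask_channel(channel: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_mask_channel` by nearest level."""
    return np.rint(channel * (_N_LABELS - 1)).astype(np.uint8)


def compose_channels(image: np.ndarray, mask: Optional[np.ndarray],
                     combo: str) -> np.ndarray:
    """Stack three channels (H, W, 3) according to the combination string."""
    key = canonical_combo(combo)
    im_channel = None
    seg_channel = None
    channels = []
    for c in key:
        if c == "i":
            if im_channel is None:
                im_channel = normalize_image(image)
            channels.append(im_channel)
        else:
            if mask is None:
                raise ValueError("combination requires a segmentation mask")
            if seg_channel is None:
                seg_channel = encode_mask_channel(mask)
            channels.append(seg_channel)
    return np.stack(channels, axis=-1)


def downsample_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling (anti-aliased) for greyscale images."""
    if factor == 1:
        return image
    h, w = image.shape
    return image[: h - h % factor, : w - w % factor].reshape(
        h // factor, factor, w // factor, factor
    ).mean(axis=(1, 3)).astype(np.float32)


def downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Stride subsampling for label masks (preserves exact label codes).

    Trailing rows/cols beyond a multiple of ``factor`` are trimmed first so
    the result is always grid-aligned with :func:`downsample_image`.
    """
    if factor == 1:
        return mask
    h, w = mask.shape
    return np.ascontiguousarray(
        mask[: h - h % factor : factor, : w - w % factor : factor]
    )


def build_dataset(
    subjects: Sequence[PhantomSubject],
    combo: str,
    downsample: int = 2,
    frames: Sequence[str] = ("ED", "ES"),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble per-image samples: each frame of each subject is one sample.

    Returns (X, y, subject_ids) with X of shape (N, H, W, 3), y = 1 for
    group B (the positive class), and subject_ids aligned with rows for
    subject-atomic resampling.
    """
    xs, ys, ids = [], [], []
    for s in subjects:
        for fr in frames:
            img = downsample_image(s.frames[fr], downsample)
            msk = downsample_mask(s.masks[fr], downsample)
            xs.append(compose_channels(img, msk, combo))
            ys.append(1 if s.group == "B" else 0)
            ids.append(s.subject_id)
    return np.stack(xs), np.array(ys), np.array(ids)


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------

def train_group_classifier(
    samples: np.ndarray,
    labels: np.ndarray,
    config: Optional[ClassifierConfig] = None,
    seed: int = 0,
) -> GroupClassifier:
    """Train the reduced residual CNN on (N, H, W, 3) samples."""
    return fit_classifier(samples, labels, config=config, seed=seed)


def evaluate_classifier(
    model: GroupClassifier, samples: np.ndarray, labels: np.ndarray
) -> Tuple[float, float, float]:
    """Accuracy, sensitivity, specificity with group B as positive class."""
    if len(samples) == 0:
        raise ValueError("empty evaluation set")
    pred = (model.predict_proba(samples) >= 0.5).astype(int)
    labels = np.asarray(labels)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc = (tp + tn) / len(labels)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return acc, sens, spec


@dataclass
class ClassificationSplit:
    """A subject-level train/test split ready for the repeat protocol."""

    train_subjects: List[PhantomSubject]
    test_subjects: List[PhantomSubject]


def repeat_audit(
    dataset: ClassificationSplit,
    combo: str,
    n_runs: int = 10,
    base_seed: int = 0,
    config: Optional[ClassifierConfig] = None,
    downsample: int = 2,
    train_fraction: float = 0.9,
    precomposed: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
    test_arrays: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> AuditSummary:
    """Train ``n_runs`` classifiers with different seeds and train/validation
    subsamples; evaluate each on the fixed test set.

    Each run draws a fresh subject-atomic training subsample (both frames of
    a subject stay together); the held-out 1 - train_fraction acts as the
    run's validation split.  ``precomposed``/``test_arrays`` allow callers
    to supply already-built arrays (e.g. cropped or blurred variants).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    key = canonical_combo(combo)
    if precomposed is None:
        x_tr, y_tr, id_tr = build_dataset(dataset.train_subjects, key, downsample)
    else:
        x_tr, y_tr, id_tr = precomposed
    if test_arrays is None:
        x_te, y_te, _ = build_dataset(dataset.test_subjects, key, downsample)
    else:
        x_te, y_te = test_arrays

    uniq = np.unique(id_tr)
    accs, sens, specs = [], [], []
    for r in range(n_runs):
        seed = base_seed + r
        rng = np.random.default_rng(seed)
        n_keep = max(2, int(round(train_fraction * len(uniq))))
        keep = set(rng.choice(uniq, size=n_keep, replace=False).tolist())
        sel = np.array([i in keep for i in id_tr])
        model = train_group_classifier(x_tr[sel], y_tr[sel], config=config, seed=seed)
        a, s, p = evaluate_classifier(model, x_te, y_te)
        accs.append(a)
        sens.append(s)
        specs.append(p)
    return AuditSummary(
        combo=key,
        accuracy=np.array(accs),
        sensitivity=np.array(sens),
        specificity=np.array(specs),
    )


def compare_audits_ttest(runs_a: Sequence[float], runs_b: Sequence[float]) -> float:
    """Two-sided two-sample Student's t-test on per-run accuracies."""
    a, b = np.asarray(runs_a, float), np.asarray(runs_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two runs per configuration")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 1.0
        raise ValueError("zero pooled variance with unequal means")
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def mean_intensity_histogram(
    cohort: Cohort, bins: int = 20, frames: Sequence[str] = ("ED", "ES")
) -> Dict[str, object]:
    """Histogram of per-image mean intensities, per group, on common bins."""
    means = {
        g: np.array([
            float(s.frames[fr].mean())
            for s in cohort.by_group(g)
            for fr in frames
        ])
        for g in ("A", "B")
    }
    allv = np.concatenate([means["A"], means["B"]])
    edges = np.histogram_bin_edges(allv, bins=bins)
    return {
        "edges": edges,
        "counts": {g: np.histogram(means[g], bins=edges)[0] for g in means},
        "means": means,
    }
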