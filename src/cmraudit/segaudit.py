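"""Segmentation bias audit: imbalance-sweep training and per-group Dice.

A small U-shaped segmenter is trained once per training-set composition
(group-B fraction 1.0 ... 0.0, constant total size) and evaluated on one
fixed, group-balanced test set.  Per-subject Dice similarity coefficients
(DSC; mean over the three foreground labels and the ED/ES frames) are
compared between groups with a Mann-Whitney U test at each fraction,
optionally after cropping all images tightly around the heart.  The gap
between group medians as a function of training imbalance is the bias
signal; running the sweep on original and cropped inputs measures how much
of the bias is removed by discarding non-heart image content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .channels import downsample_image, downsample_mask, normalize_image
from .design import ImbalanceSplit
from .interventions import crop_subject, global_crop_size
from .nn import SegmenterConfig, UNetSegmenter, fit_segmenter
from .phantom import PhantomSubject

__all__ = [
    "SweepResult",
    "subjects_to_arrays",
    "train_segmenter",
    "predict_mask",
    "dice",
    "subject_dsc",
    "per_group_dsc",
    "dsc_table",
    "mann_whitney",
    "significance_stars",
    "run_imbalance_sweep",
]

FOREGROUND = (1, 2, 3)


def _pad_to_multiple(a: np.ndarray, m: int = 4) -> np.ndarray:
    """Zero-pad trailing rows/cols so spatial dims are multiples of m (the
    U-Net's total downsampling factor)."""
    h, w = a.shape[:2]
    ph, pw = (-h) % m, (-w) % m
    if ph == 0 and pw == 0:
        return a
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (a.ndim - 2)
    return np.pad(a, pad)


def subjects_to_arrays(
    subjects: Sequence[PhantomSubject],
    downsample: int = 2,
    frames: Sequence[str] = ("ED", "ES"),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, T, subject_ids): normalized (N, H, W, 1) images and (N, H, W)
    label masks, one sample per frame, padded to the U-Net grid."""
    xs, ts, ids = [], [], []
    for s in subjects:
        for fr in frames:
            img = normalize_image(downsample_image(s.frames[fr], downsample))
            msk = downsample_mask(s.masks[fr], downsample)
            xs.append(_pad_to_multiple(img)[..., None])
            ts.append(_pad_to_multiple(msk))
            ids.append(s.subject_id)
    return np.stack(xs), np.stack(ts), np.array(ids)


def train_segmenter(
    train_subjects: Sequence[PhantomSubject],
    config: Optional[SegmenterConfig] = None,
    seed: int = 0,
    downsample: int = 2,
    return_history: bool = False,
):
    """Train the encoder-decoder segmenter on a subject collection."""
    if len(train_subjects) == 0:
        raise ValueError("empty training set")
    x, t, _ = subjects_to_arrays(train_subjects, downsample)
    return fit_segmenter(x, t, config=config, seed=seed,
                         return_history=return_history)


def predict_mask(model: UNetSegmenter, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax labels for one normalized (H, W) or (H, W, 1) image."""
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[..., None]
    return model.predict(x[None])[0]


def dice(pred: np.ndarray, gt: np.ndarray, label: int) -> float:
    """Dice similarity coefficient 2|P∩G|/(|P|+|G|) for one label; defined
    as 1.0 when the label is absent from both masks."""
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth grids differ")
    p = pred == label
    g = gt == label
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def _frame_dsc(pred: np.ndarray, gt: np.ndarray,
               labels: Sequence[int] = FOREGROUND) -> float:
    return float(np.mean([dice(pred, gt, l) for l in labels]))


def subject_dsc(
    model: UNetSegmenter,
    subject: PhantomSubject,
    downsample: int = 2,
    pooled: bool = False,
) -> float:
    """Subject-level DSC: mean over foreground labels and the two frames
    (or pooled-foreground overlap when ``pooled``)."""
    x, t, _ = subjects_to_arrays([subject], downsample)
    preds = model.predict(x)
    if pooled:
        vals = [dice(preds[i] > 0, t[i] > 0, True) for i in range(len(t))]
    else:
        vals = [_frame_dsc(preds[i], t[i]) for i in range(len(t))]
    return float(np.mean(vals))


def per_group_dsc(
    model: UNetSegmenter,
    test_subjects: Sequence[PhantomSubject],
    downsample: int = 2,
) -> Dict[str, List[float]]:
    """Per-group lists of subject-level DSCs on the fixed test set."""
    out: Dict[str, List[float]] = {"A": [], "B": []}
    x, t, ids = subjects_to_arrays(test_subjects, downsample)
    preds = model.predict(x)
    scores = np.array([_frame_dsc(preds[i], t[i]) for i in range(len(t))])
    df = pd.DataFrame({"id": ids, "dsc": scores}).groupby("id")["dsc"].mean()
    for s in test_subjects:
        out[s.group].append(float(df[s.subject_id]))
    return out


def dsc_table(
    model: UNetSegmenter,
    subjects: Sequence[PhantomSubject],
    downsample: int = 2,
) -> pd.DataFrame:
    """Per-subject DSC joined with group, for confounder analysis."""
    rows = []
    for s in subjects:
        rows.append({
            "subject_id": s.subject_id,
            "group": s.group,
            "dsc": subject_dsc(model, s, downsample),
        })
    return pd.DataFrame(rows)


def mann_whitney(dsc_a: Sequence[float], dsc_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value; exact for small tie-free samples,
    otherwise the tie-corrected normal approximation."""
    a, b = np.asarray(dsc_a, float), np.asarray(dsc_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (no_ties and len(a) + len(b) <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def significance_stars(p: float) -> str:
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class SweepResult:
    """Per-imbalance-level, per-group DSC distributions with tests."""

    intervention: str  # "original" or "cropped"
    fractions: List[float]
    dsc: Dict[float, Dict[str, List[float]]]
    p_values: Dict[float, float]
    test_ids: List[str]

    def median_gap(self, fraction: float) -> float:
        """median(group A DSC) - median(group B DSC) at one fraction."""
        d = self.dsc[fraction]
        return float(np.median(d["A"]) - np.median(d["B"]))

    def summary(self) -> pd.DataFrame:
        rows = []
        for f in self.fractions:
            d = self.dsc[f]
            p = self.p_values[f]
            rows.append({
                "fraction_b": f,
                "median_dsc_a": float(np.median(d["A"])),
                "median_dsc_b": float(np.median(d["B"])),
                "median_gap": self.median_gap(f),
                "p_value": p,
                "stars": significance_stars(p),
            })
        return pd.DataFrame(rows)


def run_imbalance_sweep(
    subjects_by_id: Mapping[str, PhantomSubject],
    splits: Sequence[ImbalanceSplit],
    test_ids: Sequence[str],
    intervention: str = "original",
    seed: int = 0,
    config: Optional[SegmenterConfig] = None,
    downsample: int = 2,
) -> SweepResult:
    """Train one segmenter per imbalance split and audit per-group DSC.

    Under the "cropped" intervention the shared crop window size is
    computed from the training pools only (never the test set) and applied
    identically to training and test subjects.
    """
    if intervention not in ("original", "cropped"):
        raise ValueError(f"unknown intervention {intervention!r}")
    test_subjects = [subjects_by_id[i] for i in test_ids]

    if intervention == "cropped":
        pool_ids = sorted({i for sp in splits for i in sp.train_ids})
        size = global_crop_size(
            m for i in pool_ids for m in subjects_by_id[i].masks.values()
        )
        cropped: Dict[str, PhantomSubject] = {}

        def get(i: str) -> PhantomSubject:
            if i not in cropped:
                cropped[i] = crop_subject(subjects_by_id[i], size)
            return cropped[i]
    else:
        def get(i: str) -> PhantomSubject:
            return subjects_by_id[i]

    test_prepared = [get(i) for i in test_ids]
    dsc: Dict[float, Dict[str, List[float]]] = {}
    pvals: Dict[float, float] = {}
    for k, sp in enumerate(splits):
        train = [get(i) for i in sp.train_ids]
        model = train_segmenter(train, config=config, seed=seed + k,
                                downsample=downsample)
        groups = per_group_dsc(model, test_prepared, downsample)
        dsc[sp.fraction_b] = groups
        pvals[sp.fraction_b] = mann_whitney(groups["A"], groups["B"])
    return SweepResult(
        intervention=intervention,
        fractions=[sp.fraction_b for sp in splits],
        dsc=dsc,
        p_values=pvals,
        test_ids=list(test_ids),
    )
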