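"""Region-localization interventions: crop tightly around the heart, or
blur the heart out.

Cropping removes everything outside the heart's bounding box (all crops in
an experiment share one window size, the largest heart bounding box in the
reference set, so inputs stay stackable).  Blurring does the opposite:
Gaussian-smoothed values are written only at heart-foreground voxels,
leaving the rest of the image bit-identical.  Comparing classifier or
segmenter behaviour across {original, cropped, blurred} localizes how much
of a group-level distributional shift lies inside versus outside the heart.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .phantom import PhantomSubject

__all__ = [
    "BoundingBox",
    "heart_bbox",
    "global_crop_size",
    "crop_to_heart",
    "crop_subject",
    "blur_heart",
    "blur_subject",
]

FOREGROUND = (1, 2, 3)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [row_min, row_max) x [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("bounding box must have positive extent")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)

    @property
    def center(self) -> Tuple[float, float]:
        return (
            (self.row_min + self.row_max) / 2.0,
            (self.col_min + self.col_max) / 2.0,
        )


def heart_bbox(mask: np.ndarray) -> BoundingBox:
    """Tight bounding box over the heart foreground labels {1, 2, 3}."""
    fg = np.isin(mask, FOREGROUND)
    if not fg.any():
        raise ValueError("mask has no heart foreground")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    return BoundingBox(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def _subject_bbox(subject: PhantomSubject) -> BoundingBox:
    """Union bbox over a subject's ED and ES masks (one window per subject)."""
    boxes = [heart_bbox(m) for m in subject.masks.values()]
    return BoundingBox(
        min(b.row_min for b in boxes),
        max(b.row_max for b in boxes),
        min(b.col_min for b in boxes),
        max(b.col_max for b in boxes),
    )


def global_crop_size(masks: Iterable[np.ndarray]) -> Tuple[int, int]:
    """Per-axis maximum of individual heart-bbox extents (the size of the
    largest heart in the reference set)."""
    heights, widths = [], []
    for m in masks:
        b = heart_bbox(m)
        heights.append(b.shape[0])
        widths.append(b.shape[1])
    if not heights:
        raise ValueError("no masks with heart foreground")
    return (max(heights), max(widths))


def _window(center: float, size: int, limit: int) -> Tuple[int, int]:
    """A length-``size`` window centred as closely as possible on ``center``,
    shifted (never shrunk) to stay within [0, limit)."""
    start = int(round(center - size / 2.0))
    start = max(0, min(start, limit - size))
    return start, start + size


def crop_to_heart(
    image: np.ndarray,
    mask: np.ndarray,
    size: Tuple[int, int],
    bbox: Optional[BoundingBox] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Crop a window of exactly ``size`` centred on the heart bbox.

    The window is shifted when clipped by an image edge so its shape never
    changes, and it always contains all heart foreground (requires ``size``
    at least the subject's own bbox extents).
    """
    b = bbox or heart_bbox(mask)
    h, w = image.shape
    if size[0] > h or size[1] > w:
        raise ValueError("crop size exceeds image size")
    if size[0] < b.shape[0] or size[1] < b.shape[1]:
        raise ValueError("crop size smaller than the subject's heart bbox")
    r0, r1 = _window(b.center[0], size[0], h)
    c0, c1 = _window(b.center[1], size[1], w)
    return image[r0:r1, c0:c1].copy(), mask[r0:r1, c0:c1].copy()


def crop_subject(subject: PhantomSubject, size: Tuple[int, int]) -> PhantomSubject:
    """Crop both frames of a subject with one shared window (union of the
    ED and ES heart bboxes), returning a new subject on the cropped grid."""
    b = _subject_bbox(subject)
    frames, masks = {}, {}
    for fr in subject.frames:
        frames[fr], masks[fr] = crop_to_heart(
            subject.frames[fr], subject.masks[fr], size, bbox=b
        )
    h, w = subject.frames[next(iter(subject.frames))].shape
    r0, _ = _window(b.center[0], size[0], h)
    c0, _ = _window(b.center[1], size[1], w)
    aux = {
        k: v[r0:r0 + size[0], c0:c0 + size[1]].copy()
        for k, v in subject.aux.items()
    }
    return PhantomSubject(
        covariates=subject.covariates,
        frames=frames,
        masks=masks,
        aux=aux,
        meta=dict(subject.meta, cropped=True),
    )


def blur_heart(image: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Write Gaussian-smoothed values only at heart-foreground pixels.

    Smoothing is computed on the full image and then masked in, so
    background pixels remain bit-identical to the input.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    fg = np.isin(mask, FOREGROUND)
    smoothed = ndimage.gaussian_filter(image.astype(np.float32), sigma)
    out = image.copy()
    out[fg] = smoothed[fg]
    return out


def blur_subject(subject: PhantomSubject, sigma: float = 4.0) -> PhantomSubject:
    frames = {
        fr: blur_heart(subject.frames[fr], subject.masks[fr], sigma)
        for fr in subject.frames
    }
    return PhantomSubject(
        covariates=subject.covariates,
        frames=frames,
        masks={k: v.copy() for k, v in subject.masks.items()},
        aux=subject.aux,
        meta=dict(subject.meta, blurred_sigma=sigma),
    )
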