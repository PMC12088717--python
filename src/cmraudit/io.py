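"""On-disk layout, configuration, and (de)serialization for phantom cohorts.

Volumes are stored as NIfTI-1 (one file per subject per frame; label masks
carry a ``_seg`` suffix, auxiliary generator masks an ``_aux-<name>``
suffix), covariates as a single RFC-4180 CSV, and a JSON manifest ties the
cohort together (subject ids, shift configuration, seed, per-subject
metadata).  Pixel indexing is 0-based row/col; the affine is identity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .nn import ClassifierConfig, SegmenterConfig
from .phantom import (
    Cohort,
    CovariateRecord,
    PhantomSubject,
    ShiftConfig,
)

__all__ = [
    "AuditConfig",
    "write_subject",
    "read_subject",
    "write_cohort",
    "read_cohort",
]

FRAMES = ("ED", "ES")
VALID_LABELS = {0, 1, 2, 3}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AuditConfig:
    """Everything needed to reproduce one full audit run.

    All seeds are explicit; the config round-trips losslessly through YAML.
    """

    n_per_group: int = 40
    seed: int = 0
    null_cohort: bool = False
    shift: ShiftConfig = field(default_factory=ShiftConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    fractions: List[float] = field(default_factory=lambda: [1.0, 0.75, 0.5, 0.25, 0.0])
    n_runs: int = 10
    n_test_pairs: Optional[int] = None  # default: ~20% of pairs
    downsample: int = 2
    blur_sigma: float = 4.0
    pca_components: int = 10
    cv_folds: int = 5
    out_dir: str = "audit_out"

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["classifier"]["lr_decay_epochs"] = list(self.classifier.lr_decay_epochs)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "AuditConfig":
        d = dict(d)
        if "shift" in d and isinstance(d["shift"], dict):
            d["shift"] = ShiftConfig(**d["shift"])
        if "classifier" in d and isinstance(d["classifier"], dict):
            c = dict(d["classifier"])
            c["lr_decay_epochs"] = tuple(c.get("lr_decay_epochs", ()))
            d["classifier"] = ClassifierConfig(**c)
        if "segmenter" in d and isinstance(d["segmenter"], dict):
            d["segmenter"] = SegmenterConfig(**d["segmenter"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AuditConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# NIfTI subject I/O
# ---------------------------------------------------------------------------

def _save_nii(arr: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))


def _load_nii(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing volume file: {path}")
    return np.asarray(nib.load(str(path)).dataobj)


def write_subject(subject: PhantomSubject, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    for fr in subject.frames:
        _save_nii(subject.frames[fr].astype(np.float32), d / f"{sid}_{fr}.nii.gz")
        _save_nii(subject.masks[fr].astype(np.uint8), d / f"{sid}_{fr}_seg.nii.gz")
    for name, m in subject.aux.items():
        _save_nii(m.astype(np.uint8), d / f"{sid}_aux-{name}.nii.gz")


def read_subject(
    directory,
    subject_id: str,
    covariates: CovariateRecord,
    meta: Optional[Dict] = None,
    aux_names=("body", "fat_ring", "ghost"),
) -> PhantomSubject:
    """Load one subject's volumes; validates grids and label codes."""
    d = Path(directory)
    frames, masks, aux = {}, {}, {}
    for fr in FRAMES:
        img = _load_nii(d / f"{subject_id}_{fr}.nii.gz").astype(np.float32)
        seg_path = d / f"{subject_id}_{fr}_seg.nii.gz"
        msk = _load_nii(seg_path).astype(np.uint8)
        if msk.shape != img.shape:
            raise ValueError(
                f"grid mismatch between image and mask for {subject_id} {fr}"
            )
        bad = set(np.unique(msk)) - VALID_LABELS
        if bad:
            raise ValueError(f"unknown label codes {sorted(bad)} in {seg_path}")
        frames[fr], masks[fr] = img, msk
    for name in aux_names:
        p = d / f"{subject_id}_aux-{name}.nii.gz"
        if p.exists():
            aux[name] = _load_nii(p).astype(bool)
    return PhantomSubject(covariates=covariates, frames=frames, masks=masks,
                          aux=aux, meta=dict(meta or {}))


def write_cohort(cohort: Cohort, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        write_subject(s, d / "volumes")
    cohort.table.to_csv(d / "covariates.csv", index=False)
    manifest = {
        "seed": cohort.seed,
        "shift": dataclasses.asdict(cohort.shift),
        "subjects": [
            {"subject_id": s.subject_id, "meta": _jsonable(s.meta)}
            for s in cohort.subjects
        ],
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(directory) -> Cohort:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    table = pd.read_csv(d / "covariates.csv")
    records = {
        r["subject_id"]: CovariateRecord(**r)
        for r in table.to_dict(orient="records")
    }
    subjects = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        subjects.append(
            read_subject(d / "volumes", sid, records[sid], meta=entry["meta"])
        )
    shift = ShiftConfig(**manifest["shift"])
    return Cohort(subjects=subjects, shift=shift, seed=manifest["seed"])


def _jsonable(meta: Dict) -> Dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        elif isinstance(v, (bool, np.bool_)):
            out[k] = bool(v)
        else:
            out[k] = v
    return out
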