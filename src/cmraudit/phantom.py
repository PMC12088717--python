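"""Synthetic two-group short-axis cine CMR phantom cohorts.

Each subject is a 2D short-axis slice at end-diastole (ED) and end-systole
(ES) with a 4-class ground-truth mask (background, LV blood pool, LV
myocardium, RV blood pool).  The generator places every group-level
distributional shift explicitly, so the location and magnitude of any
image-borne, segmentation-borne, or covariate-borne difference between the
two groups is known by construction:

* subcutaneous-fat ring thickness and intensity (image-borne, outside the
  heart),
* periodic ghosting echoes of the fat/skin layer along the phase-encode
  axis (image-borne artefact, outside the heart by default),
* heart geometry scale (segmentation-borne, off by default),
* covariate distributions (age, BMI, ...), optionally coupled to image
  features (BMI -> fat thickness, LV mass -> myocardial thickness).

With all shift deltas at zero the two groups are exchangeable in image and
mask distribution; couplings act on within-group covariate deviations only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "CovariateRecord",
    "ShiftConfig",
    "PhantomGeometry",
    "PhantomSubject",
    "Cohort",
    "default_covariate_params",
    "null_covariate_params",
    "sample_covariates",
    "render_subject",
    "inject_ghosting",
    "generate_cohort",
]

# Segmentation label codes.
LABELS = {"background": 0, "lvbp": 1, "lvm": 2, "rvbp": 3}
LABEL_NAMES = {v: k for k, v in LABELS.items()}
FOREGROUND_LABELS = (1, 2, 3)

GROUPS = ("A", "B")

#: Reference year used when coupling MRI year to artefact prevalence.
YEAR_REF = 2014


@dataclass
class CovariateRecord:
    """Demographics and cardiac-function covariates for one subject."""

    subject_id: str
    group: str  # "A" or "B" (protected-group label)
    sex: str  # "M" or "F"
    age: float  # years
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m^2
    heart_rate: float  # bpm
    lvsv: float  # mL
    lvef: float  # fraction in (0, 1)
    lvedm: float  # g
    mri_year: int
    diabetes: int = 0
    hypertension: int = 0
    hypercholesterolaemia: int = 0
    smoking: int = 0

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not (0.0 < self.lvef < 1.0):
            raise ValueError("lvef must lie in (0, 1)")
        implied = self.weight / (self.height / 100.0) ** 2
        if abs(implied - self.bmi) > 0.1:
            raise ValueError("bmi inconsistent with weight/height^2")

    def as_dict(self) -> Dict[str, object]:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "sex": self.sex,
            "age": self.age,
            "height": self.height,
            "weight": self.weight,
            "bmi": self.bmi,
            "heart_rate": self.heart_rate,
            "lvsv": self.lvsv,
            "lvef": self.lvef,
            "lvedm": self.lvedm,
            "mri_year": self.mri_year,
            "diabetes": self.diabetes,
            "hypertension": self.hypertension,
            "hypercholesterolaemia": self.hypercholesterolaemia,
            "smoking": self.smoking,
        }


@dataclass
class ShiftConfig:
    """Ground-truth specification of where and how the two groups differ.

    ``fat_thickness_delta`` and ``fat_intensity_delta`` are added to group
    B's fat ring (pixels / normalized intensity units).  Ghosting echoes are
    injected per subject with group-dependent probability
    ``ghost_prevalence``; each echo k = 1..n_echoes is a copy of the fat-ring
    intensities translated by k * ghost_spacing pixels along the
    phase-encode (row) axis and scaled by ghost_amplitude ** k.
    ``heart_shape_delta`` scales group B's heart geometry (0 = identical
    heart-shape distributions).  ``bmi_fat_coupling`` (px per kg/m^2) and
    ``lvedm_myo_coupling`` (px per g) link within-group covariate deviations
    to fat-ring and myocardial thickness.  ``year_ghost_coupling`` adds
    (mri_year - YEAR_REF) * coefficient to the ghost probability, the
    mechanism behind a spurious scan-year confounder.  ``noise_sigma`` is
    the Rician noise scale.
    """

    fat_thickness_delta: float = 2.5
    fat_intensity_delta: float = 0.15
    ghost_prevalence: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.10, "B": 0.55}
    )
    ghost_amplitude: float = 0.35
    ghost_spacing: int = 64
    n_echoes: int = 2
    heart_shape_delta: float = 0.0
    bmi_fat_coupling: float = 0.25
    lvedm_myo_coupling: float = 0.03
    year_ghost_coupling: float = 0.0
    noise_sigma: float = 0.03

    def validate(self) -> None:
        for g, p in self.ghost_prevalence.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in ghost_prevalence")
            if not (0.0 <= p <= 1.0):
                raise ValueError("ghost prevalence must lie in [0, 1]")
        if self.ghost_spacing < 1:
            raise ValueError("ghost_spacing must be >= 1 pixel")
        if self.ghost_amplitude < 0:
            raise ValueError("ghost_amplitude must be >= 0")
        if self.n_echoes < 0:
            raise ValueError("n_echoes must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def null(cls) -> "ShiftConfig":
        """A configuration under which the groups are exchangeable."""
        return cls(
            fat_thickness_delta=0.0,
            fat_intensity_delta=0.0,
            ghost_prevalence={"A": 0.0, "B": 0.0},
            ghost_amplitude=0.0,
            heart_shape_delta=0.0,
            year_ghost_coupling=0.0,
        )

    @property
    def is_null(self) -> bool:
        return (
            self.fat_thickness_delta == 0
            and self.fat_intensity_delta == 0
            and self.heart_shape_delta == 0
            and self.year_ghost_coupling == 0
            and (
                self.ghost_amplitude == 0
                or len(set(self.ghost_prevalence.values())) <= 1
            )
        )


@dataclass
class PhantomGeometry:
    """Fixed rendering geometry (pixel units) and tissue intensities.

    Defaults place the heart so that its bounding box excludes the fat ring
    and the first ghost-echo band, mirroring short-axis anatomy where
    subcutaneous fat lies at the body surface, well away from the heart.
    """

    size: int = 96
    body_semi_row: float = 38.0
    body_semi_col: float = 44.0
    fat_thickness_base: float = 4.0
    lung_semi: tuple = (12.0, 9.0)
    lung_row: float = 38.0
    lung_col_offset: float = 19.0
    lv_center: tuple = (52.0, 42.0)
    lv_epi_radius: float = 12.0
    myo_thickness_base: float = 3.5
    rv_gap: float = 1.5
    rv_radius_frac: float = 0.92
    contraction: float = 0.75  # ES endocardial radius scale
    intensity_tissue: float = 0.35
    intensity_fat: float = 0.70
    intensity_lung: float = 0.12
    intensity_lvbp: float = 0.85
    intensity_lvm: float = 0.40
    intensity_rvbp: float = 0.82


@dataclass
class PhantomSubject:
    """One synthetic subject: paired frames, masks, covariates, and the
    generator-private auxiliary masks used as ground truth for attribution
    scoring (disjoint from heart foreground by construction)."""

    covariates: CovariateRecord
    frames: Dict[str, np.ndarray]  # {"ED": HxW float32, "ES": ...}
    masks: Dict[str, np.ndarray]  # {"ED": HxW uint8, "ES": ...}
    aux: Dict[str, np.ndarray]  # {"body", "fat_ring", "ghost"} bool masks
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def subject_id(self) -> str:
        return self.covariates.subject_id

    @property
    def group(self) -> str:
        return self.covariates.group

    def heart_mask(self, frame: str) -> np.ndarray:
        return self.masks[frame] > 0


@dataclass
class Cohort:
    subjects: List[PhantomSubject]
    shift: ShiftConfig
    seed: int

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([s.covariates.as_dict() for s in self.subjects])

    def by_group(self, group: str) -> List[PhantomSubject]:
        return [s for s in self.subjects if s.group == group]

    def __len__(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# Covariate sampling
# ---------------------------------------------------------------------------

def default_covariate_params() -> Dict[str, Dict[str, object]]:
    """Per-group covariate distributions.

    Age/height/BMI means and SDs are plausible values for two adult
    imaging-cohort subpopulations; weight is derived from BMI and height
    so the record stays internally consistent.  Cardiac
    covariates and comorbidity prevalences are plausible population values;
    LVEDM is deliberately identical across groups so ground-truth masks
    carry no group signal unless ``heart_shape_delta`` is set.  MRI-year
    distributions differ (group A scanned earlier on average), recreating a
    spurious scan-year confounder scenario.
    """
    common = {
        "heart_rate": (68.0, 11.0),
        "lvsv": (85.0, 17.0),
        "lvef": (0.59, 0.06),
        "lvedm": (87.0, 20.0),
    }
    return {
        "A": {
            "age": (58.9, 7.0),
            "height": (171.3, 9.1),
            "bmi": (26.9, 4.6),
            **common,
            "mri_year": {2014: 0.30, 2015: 0.30, 2016: 0.20, 2017: 0.12, 2018: 0.08},
            "diabetes": 0.03,
            "hypertension": 0.25,
            "hypercholesterolaemia": 0.15,
            "smoking": 0.35,
        },
        "B": {
            "age": (58.8, 6.9),
            "height": (169.4, 9.2),
            "bmi": (28.6, 5.1),
            **common,
            "mri_year": {2014: 0.08, 2015: 0.12, 2016: 0.20, 2017: 0.30, 2018: 0.30},
            "diabetes": 0.10,
            "hypertension": 0.40,
            "hypercholesterolaemia": 0.20,
            "smoking": 0.30,
        },
    }


def null_covariate_params() -> Dict[str, Dict[str, object]]:
    """Identical (pooled) covariate distributions for both groups, for null
    cohorts in which covariates as well as images must be exchangeable."""
    pooled = {
        "age": (58.9, 7.0),
        "height": (170.4, 9.22),
        "bmi": (27.7, 4.9),
        "heart_rate": (68.0, 11.0),
        "lvsv": (85.0, 17.0),
        "lvef": (0.59, 0.06),
        "lvedm": (87.0, 20.0),
        "mri_year": {2014: 0.19, 2015: 0.21, 2016: 0.20, 2017: 0.21, 2018: 0.19},
        "diabetes": 0.06,
        "hypertension": 0.32,
        "hypercholesterolaemia": 0.17,
        "smoking": 0.32,
    }
    return {"A": dict(pooled), "B": dict(pooled)}


_NORMAL_COVS = ("age", "height", "bmi", "heart_rate", "lvsv", "lvef", "lvedm")
_BINARY_COVS = ("diabetes", "hypertension", "hypercholesterolaemia", "smoking")


def _draw_normal(mean: float, sd: float, rng: np.random.Generator,
                 lo: float = -np.inf, hi: float = np.inf) -> float:
    if sd < 0:
        raise ValueError("negative SD")
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_covariates(
    group: str,
    params: Optional[Mapping[str, Mapping[str, object]]] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    subject_id: str = "sub-0000",
    sex: Optional[str] = None,
) -> CovariateRecord:
    """Draw one covariate record from the given group's distributions.

    ``params[group]`` maps each covariate to a (mean, sd) pair, a Bernoulli
    probability (comorbidity flags), or a {year: prob} table (mri_year).
    Weight is derived from BMI and height so the BMI identity holds exactly.
    """
    if params is None:
        params = default_covariate_params()
    if group not in params:
        raise ValueError(f"unknown group label {group!r}")
    if rng is None:
        rng = np.random.default_rng()
    p = params[group]

    vals = {}
    for name in _NORMAL_COVS:
        mean, sd = p[name]
        lo, hi = {
            "age": (18.0, 100.0),
            "height": (120.0, 220.0),
            "bmi": (14.0, 60.0),
            "heart_rate": (35.0, 150.0),
            "lvsv": (30.0, 180.0),
            "lvef": (0.25, 0.80),
            "lvedm": (30.0, 220.0),
        }[name]
        vals[name] = _draw_normal(mean, sd, rng, lo, hi)

    years = p["mri_year"]
    yr_keys = sorted(years)
    probs = np.array([years[k] for k in yr_keys], dtype=float)
    probs = probs / probs.sum()
    mri_year = int(rng.choice(yr_keys, p=probs))

    flags = {name: int(rng.random() < float(p[name])) for name in _BINARY_COVS}

    if sex is None:
        sex = "M" if rng.random() < 0.5 else "F"

    weight = vals["bmi"] * (vals["height"] / 100.0) ** 2
    rec = CovariateRecord(
        subject_id=subject_id,
        group=group,
        sex=sex,
        age=vals["age"],
        height=vals["height"],
        weight=weight,
        bmi=vals["bmi"],
        heart_rate=vals["heart_rate"],
        lvsv=vals["lvsv"],
        lvef=vals["lvef"],
        lvedm=vals["lvedm"],
        mri_year=mri_year,
        **flags,
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(size: int, center, semi_row: float, semi_col: float) -> np.ndarray:
    rr, cc = np.ogrid[:size, :size]
    return (
        ((rr - center[0]) / max(semi_row, 1e-9)) ** 2
        + ((cc - center[1]) / max(semi_col, 1e-9)) ** 2
    ) <= 1.0


def _disc_mask(size: int, center, radius: float) -> np.ndarray:
    return _ellipse_mask(size, center, radius, radius)


def inject_ghosting(
    image: np.ndarray,
    ring_mask: np.ndarray,
    amplitude: float,
    spacing: int,
    n_echoes: int,
) -> tuple:
    """Add periodic ghost echoes of the masked ring along the phase-encode
    (row) axis.

    Echo k (k = 1..n_echoes) is the ring-masked intensity pattern translated
    by k*spacing rows and scaled by amplitude**k; echoes translated beyond
    the grid are clipped.  Returns ``(image_with_ghosts, ghost_support)``
    where the support is the boolean union of the translated ring masks.
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1 pixel")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    out = image.copy()
    support = np.zeros(image.shape, dtype=bool)
    if amplitude == 0 or n_echoes == 0:
        return out, support
    h = image.shape[0]
    ring_vals = np.where(ring_mask, image, 0.0)
    for k in range(1, n_echoes + 1):
        off = k * spacing
        if off >= h:
            break
        scale = amplitude ** k
        out[off:, :] += scale * ring_vals[: h - off, :]
        support[off:, :] |= ring_mask[: h - off, :]
    return out, support


def _render_noiseless(
    cov: CovariateRecord,
    shift: ShiftConfig,
    geom: PhantomGeometry,
    group_means: Mapping[str, Mapping[str, float]],
) -> tuple:
    """Render both frames without noise or ghosting.

    Returns (frames, masks, aux, meta).  Structures are painted in order
    (body fat -> tissue -> lungs -> heart) so later structures overwrite
    earlier ones and the label masks track the paint order exactly.
    """
    size = geom.size
    g = cov.group
    is_b = g == "B"

    gm = group_means[g]
    fat_t = (
        geom.fat_thickness_base
        + shift.bmi_fat_coupling * (cov.bmi - gm["bmi"])
        + (shift.fat_thickness_delta if is_b else 0.0)
    )
    fat_t = float(np.clip(fat_t, 0.5, 12.0))
    fat_i = geom.intensity_fat + (shift.fat_intensity_delta if is_b else 0.0)

    myo_t = (
        geom.myo_thickness_base
        + shift.lvedm_myo_coupling * (cov.lvedm - gm["lvedm"])
    )
    myo_t = float(np.clip(myo_t, 1.5, 8.0))

    scale = 1.0 + (shift.heart_shape_delta if is_b else 0.0)
    r_epi = geom.lv_epi_radius * scale
    r_endo = max(r_epi - myo_t, 2.0)
    lv_c = geom.lv_center
    rv_r = geom.rv_radius_frac * r_epi
    rv_c = (lv_c[0], lv_c[1] - (r_epi + geom.rv_gap + rv_r * 0.35))
    if lv_c[0] + r_epi >= size or rv_c[1] - rv_r < 0:
        raise ValueError("heart geometry exceeds image bounds")

    body = _ellipse_mask(size, (size / 2, size / 2), geom.body_semi_row, geom.body_semi_col)
    inner = _ellipse_mask(
        size, (size / 2, size / 2), geom.body_semi_row - fat_t, geom.body_semi_col - fat_t
    )
    fat_ring = body & ~inner

    lung_l = _ellipse_mask(
        size, (geom.lung_row, size / 2 - geom.lung_col_offset), *geom.lung_semi
    )
    lung_r = _ellipse_mask(
        size, (geom.lung_row, size / 2 + geom.lung_col_offset), *geom.lung_semi
    )
    lungs = (lung_l | lung_r) & inner

    frames: Dict[str, np.ndarray] = {}
    masks: Dict[str, np.ndarray] = {}
    for frame in ("ED", "ES"):
        contr = 1.0 if frame == "ED" else geom.contraction
        lvbp = _disc_mask(size, lv_c, r_endo * contr)
        epi = _disc_mask(size, lv_c, r_epi)
        lvm = epi & ~lvbp
        rv_full = _disc_mask(size, rv_c, rv_r * (1.0 if frame == "ED" else math.sqrt(contr)))
        rvbp = rv_full & ~_disc_mask(size, lv_c, r_epi + geom.rv_gap)

        img = np.zeros((size, size), dtype=np.float32)
        img[fat_ring] = fat_i
        img[inner] = geom.intensity_tissue
        img[lungs] = geom.intensity_lung
        img[rvbp] = geom.intensity_rvbp
        img[lvm] = geom.intensity_lvm
        img[lvbp] = geom.intensity_lvbp

        mask = np.zeros((size, size), dtype=np.uint8)
        mask[rvbp] = LABELS["rvbp"]
        mask[lvm] = LABELS["lvm"]
        mask[lvbp] = LABELS["lvbp"]
        frames[frame] = img
        masks[frame] = mask

    # Keep the attribution ground truth disjoint from heart foreground even
    # for extreme fat thickness / heart scale draws.
    heart_any = (masks["ED"] > 0) | (masks["ES"] > 0)
    aux = {"body": body, "fat_ring": fat_ring & ~heart_any}
    meta = {
        "fat_thickness": fat_t,
        "fat_intensity": fat_i,
        "myo_thickness": myo_t,
        "heart_scale": scale,
    }
    return frames, masks, aux, meta


def _rician(img: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the complex Gaussian-perturbed signal (MR magnitude
    image noise model)."""
    if sigma == 0:
        return img
    n1 = rng.normal(0.0, sigma, img.shape)
    n2 = rng.normal(0.0, sigma, img.shape)
    return np.sqrt((img + n1) ** 2 + n2 ** 2).astype(np.float32)


def render_subject(
    cov: CovariateRecord,
    shift: ShiftConfig,
    rng: Optional[np.random.Generator] = None,
    geometry: Optional[PhantomGeometry] = None,
    params: Optional[Mapping[str, Mapping[str, object]]] = None,
) -> PhantomSubject:
    """Render one subject's ED/ES frames, masks, and auxiliary masks.

    Ghosting is injected per subject with group-dependent probability
    (optionally modulated by MRI year); Rician noise is applied last so the
    noiseless geometry fully determines the label masks.
    """
    shift.validate()
    if rng is None:
        rng = np.random.default_rng()
    geom = geometry or PhantomGeometry()
    if params is None:
        params = default_covariate_params()
    group_means = {
        g: {"bmi": params[g]["bmi"][0], "lvedm": params[g]["lvedm"][0]}
        for g in params
    }

    frames, masks, aux, meta = _render_noiseless(cov, shift, geom, group_means)

    p_ghost = shift.ghost_prevalence.get(cov.group, 0.0)
    p_ghost = float(np.clip(
        p_ghost + shift.year_ghost_coupling * (cov.mri_year - YEAR_REF), 0.0, 1.0
    ))
    has_ghost = bool(rng.random() < p_ghost)
    ghost_support = np.zeros((geom.size, geom.size), dtype=bool)
    if has_ghost and shift.ghost_amplitude > 0:
        for frame in frames:
            frames[frame], sup = inject_ghosting(
                frames[frame],
                aux["fat_ring"],
                shift.ghost_amplitude,
                shift.ghost_spacing,
                shift.n_echoes,
            )
            ghost_support |= sup
    aux["ghost"] = ghost_support
    meta["has_ghost"] = has_ghost

    for frame in frames:
        frames[frame] = _rician(frames[frame], shift.noise_sigma, rng)

    return PhantomSubject(covariates=cov, frames=frames, masks=masks, aux=aux, meta=meta)


def generate_cohort(
    n_per_group: int,
    shift: Optional[ShiftConfig] = None,
    seed: int = 0,
    params: Optional[Mapping[str, Mapping[str, object]]] = None,
    geometry: Optional[PhantomGeometry] = None,
) -> Cohort:
    """Generate an equal-sized, sex-balanced two-group cohort.

    Each group gets ceil(n/2) males and floor(n/2) females (the extra
    subject for odd n is male, deterministically).  Fully reproducible from
    ``seed``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    shift = shift if shift is not None else ShiftConfig()
    shift.validate()
    params = params or default_covariate_params()
    rng = np.random.default_rng(seed)

    n_male = (n_per_group + 1) // 2
    subjects: List[PhantomSubject] = []
    idx = 0
    for group in GROUPS:
        for i in range(n_per_group):
            sex = "M" if i < n_male else "F"
            cov = sample_covariates(
                group, params, rng, subject_id=f"sub-{idx:04d}", sex=sex
            )
            subjects.append(
                render_subject(cov, shift, rng, geometry=geometry, params=params)
            )
            idx += 1
    return Cohort(subjects=subjects, shift=shift, seed=seed)
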