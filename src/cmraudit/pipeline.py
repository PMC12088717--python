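"""End-to-end audit orchestration.

``run_full_audit`` executes the complete investigation on one generated
cohort: channel-combination classification (image vs segmentation
separability), crop/blur localization, GradCAM region taxonomy, the
imbalance sweep on original and cropped inputs, latent-space probing of
every sweep encoder, and the covariate confounder regressions.  It returns
a single structured report (also written as JSON when ``out_dir`` is set)
in which every number is traceable to the recorded config and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import channels, confounders, design, latent, saliency, segaudit
from .channels import ClassificationSplit, build_dataset
from .interventions import blur_subject, crop_subject, global_crop_size
from .io import AuditConfig
from .phantom import generate_cohort, null_covariate_params, ShiftConfig

log = logging.getLogger("cmraudit")

__all__ = ["run_full_audit"]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.time()
            try:
                out = fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"audit stage '{name}' failed: {e}") from e
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("classification")
def _classification_stage(split, cfg: AuditConfig) -> Dict:
    out = {}
    for combo in channels.COMBOS:
        summary = channels.repeat_audit(
            split, combo, n_runs=cfg.n_runs, base_seed=cfg.seed,
            config=cfg.classifier, downsample=cfg.downsample,
        )
        out[channels.COMBOS[combo]] = summary.as_dict()
    return out


@_stage("interventions")
def _intervention_stage(split, cfg: AuditConfig) -> Dict:
    size = global_crop_size(
        m for s in split.train_subjects for m in s.masks.values()
    )
    crop_split = ClassificationSplit(
        [crop_subject(s, size) for s in split.train_subjects],
        [crop_subject(s, size) for s in split.test_subjects],
    )
    blur_split = ClassificationSplit(
        [blur_subject(s, cfg.blur_sigma) for s in split.train_subjects],
        [blur_subject(s, cfg.blur_sigma) for s in split.test_subjects],
    )
    out = {}
    for name, sp in (("cropped", crop_split), ("blurred", blur_split)):
        summary = channels.repeat_audit(
            sp, "iii", n_runs=cfg.n_runs, base_seed=cfg.seed,
            config=cfg.classifier, downsample=cfg.downsample,
        )
        out[name] = summary.as_dict()
    return out


@_stage("saliency")
def _saliency_stage(split, cfg: AuditConfig) -> Dict:
    x, y, _ = build_dataset(split.train_subjects, "iii", cfg.downsample)
    model = channels.train_group_classifier(
        x, y, config=cfg.classifier, seed=cfg.seed
    )
    tax = saliency.cohort_attribution_summary(
        model, split.test_subjects, downsample=cfg.downsample
    )
    return {"fractions": tax.fractions}


@_stage("sweep")
def _sweep_stage(cohort, split, cfg: AuditConfig) -> Dict:
    by_id = {s.subject_id: s for s in cohort.subjects}
    train_by_group = {
        g: [s.subject_id for s in split.train_subjects if s.group == g]
        for g in ("A", "B")
    }
    test_ids = [s.subject_id for s in split.test_subjects]
    splits = design.imbalance_subsets(
        train_by_group, cfg.fractions, seed=cfg.seed, test_ids=test_ids
    )
    out = {}
    results = {}
    for intervention in ("original", "cropped"):
        res = segaudit.run_imbalance_sweep(
            by_id, splits, test_ids, intervention=intervention,
            seed=cfg.seed, config=cfg.segmenter, downsample=cfg.downsample,
        )
        results[intervention] = res
        out[intervention] = res.summary().to_dict(orient="records")
    return out, results, splits, by_id, test_ids


@_stage("probe")
def _probe_stage(by_id, splits, test_ids, cfg: AuditConfig) -> Dict:
    test_subjects = [by_id[i] for i in test_ids]
    out = {}
    for k, sp in enumerate(splits):
        model = segaudit.train_segmenter(
            [by_id[i] for i in sp.train_ids], config=cfg.segmenter,
            seed=cfg.seed + k, downsample=cfg.downsample,
        )
        z, y = latent.extract_cohort_latents(model, test_subjects, cfg.downsample)
        ncomp = min(cfg.pca_components, z.shape[0], z.shape[1])
        red, _ = latent.pca_reduce(z, ncomp)
        out[f"{sp.fraction_b:.2f}"] = latent.probe_accuracy(
            red, y, cv_folds=cfg.cv_folds, seed=cfg.seed
        )
    return out


@_stage("confounders")
def _confounder_stage(cohort, split, sweep_results, cfg: AuditConfig) -> Dict:
    # regress DSC (evenly balanced training composition) on covariates
    balanced = sweep_results["original"]
    frac = min(balanced.fractions, key=lambda f: abs(f - 0.5))
    table = cohort.table.set_index("subject_id")
    out = {"characteristics": confounders.cohort_characteristic_tests(
        cohort.table).to_dict(orient="records")}
    test_ids = balanced.test_ids
    dsc_by_id = {}
    i_a = i_b = 0
    by_id = {s.subject_id: s for s in cohort.subjects}
    for sid in test_ids:
        g = by_id[sid].group
        if g == "A":
            dsc_by_id[sid] = balanced.dsc[frac]["A"][i_a]
            i_a += 1
        else:
            dsc_by_id[sid] = balanced.dsc[frac]["B"][i_b]
            i_b += 1
    for g in ("A", "B"):
        ids = [i for i in test_ids if by_id[i].group == g]
        cov = table.loc[ids]
        dsc = [dsc_by_id[i] for i in ids]
        try:
            rep = confounders.fit_dsc_regression(dsc, cov, group=g)
            out[f"regression_{g}"] = rep.as_frame().to_dict(orient="records")
        except ValueError as e:
            out[f"regression_{g}"] = {"skipped": str(e)}
    return out


def run_full_audit(config: AuditConfig, out_dir: Optional[str] = None) -> Dict:
    """Run every audit stage on one generated cohort and bundle the report."""
    cfg = config
    params = null_covariate_params() if cfg.null_cohort else None
    shift = ShiftConfig.null() if cfg.null_cohort else cfg.shift
    cohort = generate_cohort(cfg.n_per_group, shift, seed=cfg.seed, params=params)

    match = design.match_pairs(cohort, seed=cfg.seed)
    n_test = cfg.n_test_pairs or max(2, len(match.pairs) // 5)
    train_ids, test_ids = design.split_pairs(match.pairs, n_test, seed=cfg.seed)
    by_id = {s.subject_id: s for s in cohort.subjects}
    split = ClassificationSplit(
        [by_id[i] for i in train_ids], [by_id[i] for i in test_ids]
    )

    report: Dict = {
        "config": cfg.to_dict(),
        "n_pairs": len(match.pairs),
        "n_unmatched": len(match.unmatched),
        "classification": _classification_stage(split, cfg),
        "interventions": _intervention_stage(split, cfg),
        "saliency": _saliency_stage(split, cfg),
    }
    sweep_out, sweep_results, splits, by_id, sweep_test_ids = _sweep_stage(
        cohort, split, cfg
    )
    report["sweep"] = sweep_out
    report["latent_probe"] = _probe_stage(by_id, splits, sweep_test_ids, cfg)
    report["confounders"] = _confounder_stage(cohort, split, sweep_results, cfg)

    iii = report["classification"]["Im-Im-Im"]
    sss = report["classification"]["Seg-Seg-Seg"]
    report["headline"] = {
        "image_accuracy": iii["accuracy_mean"],
        "segmentation_accuracy": sss["accuracy_mean"],
        "cropped_accuracy": report["interventions"]["cropped"]["accuracy_mean"],
        "blurred_accuracy": report["interventions"]["blurred"]["accuracy_mean"],
    }

    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
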