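# cmraudit

Fairness auditing of AI cardiac MR (CMR) segmentation on synthetic
short-axis phantoms in which every between-group difference is known by
construction.

AI segmentation models trained on imbalanced cohorts can perform worse
for under-represented protected groups even when the anatomy being
segmented is identical.  Diagnosing *why* requires knowing where the
group signal lives — in the images, in the segmentations, near the heart
or far from it — which is impossible to establish on real data where the
ground-truth shift is unknown.  `cmraudit` replaces the clinical cohort
with a controllable phantom generator: two groups (A/B) share the same
heart anatomy distribution while group-specific image features
(subcutaneous-fat ring brightness/thickness, phase-encode ghosting
artefacts) and covariate couplings are injected with known magnitude.
Every audit conclusion can therefore be validated against the planted
mechanism.

## What the audit measures

1. **Channel separability** — a small CNN classifies group from
   three-channel stacks that are any mix of normalized image (Im) and
   intensity-encoded ground-truth segmentation (Seg) channels
   (Im-Im-Im … Seg-Seg-Seg).  High Im accuracy with chance-level Seg
   accuracy localizes the shift to the images, not the anatomy.
2. **Interventions** — cropping to a tight heart window or blurring the
   heart region tests whether the image cue lies inside or outside the
   heart.
3. **Saliency taxonomy** — GradCAM attributions from the classifier are
   labelled by region (heart / non-heart body / acquisition artefact /
   other) to name the cue directly.
4. **Imbalance sweep** — U-Net segmenters trained at training-set group
   fractions 0…100 % quantify the DSC bias induced by under-representation,
   and repeating the sweep on cropped inputs tests whether removing
   non-heart cues removes the bias.
5. **Latent probing** — linear probes on segmenter bottleneck features
   measure how strongly group identity is encoded even when DSC is
   unaffected.
6. **Confounder regression** — per-group OLS of subject DSC on
   covariates recovers the planted covariate→image-feature→DSC
   mechanisms and stays silent under a null mechanism.

## Usage

Command line (`cmr-audit --help` lists all subcommands):

```bash
cmr-audit generate --seed 7 --n-per-group 50 --out-dir cohort/
cmr-audit classify --seed 7 --combo iii        # group classification audit
cmr-audit intervene --seed 7 --mode crop       # crop/blur intervention audit
cmr-audit saliency --seed 7                    # GradCAM region taxonomy
cmr-audit sweep --seed 7                       # imbalance sweep (DSC bias)
cmr-audit probe --seed 7                       # latent-space probing
cmr-audit confound --seed 7                    # covariate regressions
cmr-audit full --seed 7 --out-dir report/      # everything, one JSON report
```

Python:

```python
from cmraudit.phantom import ShiftConfig, generate_cohort
from cmraudit.pipeline import run_full_audit

cohort = generate_cohort(n_per_group=50, shift=ShiftConfig(), seed=7)
report = run_full_audit(seed=7)
```

## Package layout

| Module | Contents |
| --- | --- |
| `cmraudit.phantom` | synthetic cohort generator: geometry, covariates, group shifts, ghosting |
| `cmraudit.design` | covariate-matched pairing, pair-atomic splits, imbalance subsets |
| `cmraudit.channels` | channel composition, group classifier training, repeat-audit protocol |
| `cmraudit.interventions` | crop-to-heart and blur-heart transforms |
| `cmraudit.saliency` | GradCAM and the region taxonomy |
| `cmraudit.segaudit` | U-Net training, DSC, Mann-Whitney tests, imbalance sweep |
| `cmraudit.latent` | bottleneck feature extraction, PCA, linear probes |
| `cmraudit.confounders` | per-group DSC regressions, cohort characteristic tests, mechanism-known DSC simulator |
| `cmraudit.nn` | numpy layers with hand-written backward passes, classifier and U-Net models |
| `cmraudit.io` | cohort/subject (de)serialization, YAML audit configs |
| `cmraudit.pipeline` | end-to-end orchestration with a traceable JSON report |

See `docs/methods.md` for the statistical and modelling choices.
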