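# Methods

This note records the modelling and statistical choices behind each audit
stage.  Everything runs on one CPU core with numpy-implemented networks;
all randomness flows from user-supplied integer seeds through
`numpy.random.default_rng`.

## Synthetic cohort

Each subject is a 96×96 short-axis slice at two cardiac phases (ED, ES)
with a 4-class ground-truth mask (0 background, 1 LV blood pool, 2 LV
myocardium, 3 RV blood pool).  Anatomy (chamber radii, myocardial
thickness, ES contraction) is drawn from a shared distribution for both
groups, so segmentations carry no group signal by construction.  Group
shifts are injected only into the images:

- **Fat ring** — a subcutaneous ring at the body boundary whose
  thickness and intensity can differ by group (`fat_thickness_delta`,
  `fat_intensity_delta`); thickness is additionally coupled to BMI.
- **Ghosting** — a phase-encode ghost: attenuated, shifted echoes of the
  body added along the row axis with configurable per-group prevalence,
  amplitude, and echo spacing; prevalence can be coupled to MRI year.
- **Heart intensity delta** — optional within-heart cue, off by default.

Covariates (age, height, weight, BMI, heart rate, LV volumes/mass,
comorbidity flags, MRI year) are sampled per group with configurable
means; `weight` is derived exactly as `bmi × (height/100)²`.  Rician-like
noise is added last.  Auxiliary masks (`body`, `fat_ring`, `ghost`)
record where each injected feature actually landed, enabling exact
validation of downstream attributions.  `ShiftConfig.null()` plus
`null_covariate_params()` produces exchangeable groups for negative
controls.

## Cohort design

Subjects are matched across groups one-to-one on sex and nearest age/BMI
(greedy nearest-neighbour with gap limits), and all train/test splits
are *pair-atomic*: both members of a matched pair land on the same side,
so test sets are balanced and matched.  Training-set imbalance is
produced by `imbalance_subsets`, which replaces a fraction of group-A
training subjects with group-B ones at fractions {0, ¼, ½, ¾, 1} while
holding total size fixed; subsets are nested so the only thing that
varies along the sweep is group composition.

## Group classifier and repeat protocol

The classifier is a small residual-style CNN (stem + 2 strided stages,
BatchNorm/ReLU, global average pooling, linear head) trained with SGD +
momentum on binary cross-entropy, input 48×48×3 (2× block-mean
downsampled images; stride-subsampled masks, trimmed identically so the
two grids stay aligned).  Each configuration is trained 10 times
(acceptance: 5) with different seeds and 90 % subject-atomic training
subsamples; accuracy/sensitivity/specificity are reported as mean (SD)
over runs, and configurations are compared with a two-sided two-sample
Student's t-test on per-run accuracies.

Channel stacks: each of three channels is either the min-max-normalized
image or the mask encoded as equispaced intensities {0, ⅓, ⅔, 1}.
Min-max normalization is deliberate: it makes absolute brightness a
relative quantity, so a bright far-field structure rescales the heart —
a realistic preprocessing interaction the audit is designed to surface.

## Interventions

- **Crop-to-heart**: a single crop window sized to the largest heart
  bounding box across the cohort, shifted (never shrunk) at image
  borders, applied to images, masks, and auxiliary masks alike.
- **Blur-heart**: Gaussian blur applied inside the heart mask only,
  background bit-identical.

Cropping removes non-heart cues (fat ring, ghosts); blurring degrades
heart-interior ones.  Classifier accuracy at chance after cropping but
unchanged after blurring localizes the group signal outside the heart.

## Saliency taxonomy

GradCAM is computed at a selectable feature stage.  The default last
stage has an effectively global receptive field at the 12×12 grid (and a
spatially uniform head gradient under global average pooling), which
smears thin-structure evidence; attribution for localization therefore
uses the full-resolution stem stage (`layer=0`), whose 3×3 receptive
field can resolve the fat ring and ghost bands.  The attribution peak is
assigned a region label with precedence artefact > heart > non-heart
body > other, on ghost/body supports dilated by 2 px to absorb
upsampling and receptive-field smearing.  Cohort summaries report the
fraction of attribution maps peaking in each region.

## Segmentation audit

The segmenter is a small U-Net (2 down / 2 up stages, skip connections,
nearest-neighbour upsampling) trained with SGD on a combined soft-Dice +
cross-entropy loss, with ±3 px translation augmentation.  Performance is
mean foreground DSC per subject (both frames).  Group differences use
the Mann-Whitney U test (exact for small samples, normal approximation
otherwise).  The imbalance sweep trains one segmenter per fraction and
reports the median DSC gap (group A − group B) on the fixed matched test
set; the cropped variant re-runs the identical sweep on crop-to-heart
inputs with the window size fixed from the training cohort.

## Latent probing

Bottleneck (deepest encoder) activations are globally average-pooled per
subject, PCA-reduced, and probed with L2-regularized logistic regression
under stratified cross-validation.  Probe accuracy ≫ chance on shifted
cohorts — even for segmenters whose DSC shows no group gap — shows the
group identity is encoded in the features; null cohorts stay at chance.

## Confounder analysis

Per-group OLS regresses subject DSC on standardized covariates jointly;
coefficients are standardized β with two-sided p-values.  The derived
covariate `weight` is excluded from regression adjustment sets (it is an
exact function of BMI and height, so including it makes the design
near-collinear and arbitrarily splits the BMI effect); it still appears
in the cohort-characteristics table (group means (SD), Student's
t-tests).  Calibration uses a mechanism-known DSC simulator that maps
each subject's realized ghost presence and fat thickness to DSC through
a linear model plus noise, so sign recovery and null false-positive
rates can be checked against ground truth.

## Verification strategy

Unit tests validate each primitive against an independent oracle:
convolution vs `scipy.ndimage`, gradients vs central differences, DSC vs
brute-force counting, bounding boxes vs coordinate scans, GradCAM vs a
closed-form toy model, Mann-Whitney vs exact enumeration, PCA/probes vs
scikit-learn, regressions vs known planted signs.  Property-based tests
(hypothesis) cover invariants (Dice symmetry/bounds, encoding
round-trips, subset-count conservation).  `tests/test_acceptance.py`
checks the end-to-end scientific claims on cohorts where the truth is
known by construction, and `scripts/acceptance.py` reproduces the
headline quantities from a single seed.
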