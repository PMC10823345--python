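# Methods

## Problem and scope

Brain metastases (BMs) on contrast-enhanced black-blood (BB) T1-weighted MRI
appear as bright quasi-spherical foci against a dark vascular background.
Automated detection is complicated by two bright mimics — incompletely
suppressed vessels and the choroid plexus — and clinically useful
segmentation must exclude non-enhancing necrotic cores, because response
criteria measure solid enhancing tumour only. This package implements the
full chain (segmentation network → FP suppression → lesion-level metrics →
volumetric response classification → rater agreement) in a form that runs
and verifies end to end on synthetic phantoms.

## Network

A 3D encoder/decoder with `n_levels` resolutions (default 4), channel width
doubling from `base_channels` (default 16). Each encoder block is

    pointwise (C→C) → [depthwise 13³ → norm] + [depthwise 5³ → norm]
                    → GELU → pointwise (C→C)

The large depthwise kernel supplies the wide effective receptive field that
distinguishes an isolated sphere from a tube crossing the slab; the parallel
small kernel is the optimisation aid that structural re-parameterization
requires. Fusion folds each normalisation into its kernel,

    w' = w · γ / √(σ² + ε),   b' = β − μ · γ / √(σ² + ε),

zero-pads the small kernel to the large edge and sums branches. Fused and
two-branch forward passes agree to float rounding (verified to 1e-4 in
float32, 1e-10 in float64). Downsampling is a stride-2 depthwise 3³
convolution plus a pointwise channel doubling; upsampling is nearest
repetition followed by a fixed separable [¼, ½, ¼] smoothing — i.e.
trilinear interpolation up to boundary handling, chosen for its exact cheap
adjoint — plus a pointwise mix. Skip connections concatenate encoder
features at the matching scale.

Multiscale highlighting of foregrounds (MHF) is realised as deep
supervision: a two-channel softmax head at every coarse decoder scale
s = 1..n_levels−1, trained against the ground truth max-pooled s times
(max, never mean, so a single foreground voxel survives to every scale).
Auxiliary losses decay geometrically with weight `aux_loss_decay^s`
(default 0.5). A multiplicative alternative (`mhf_mode="gating"`, decoder
features scaled by 1 + foreground probability) is exposed behind a config
flag; deep supervision is the default because it adds no inference cost and
its targets are exactly defined.

The loss is cross-entropy plus soft Dice (smoothing ε = 1e-5) at the full
scale and at every supervised scale. Optimisation is Adam at lr 1e-3. These
training hyperparameters, the normalisation type (batch-norm over batch and
space with running statistics), and the kernel pair are free configuration
with the defaults stated here.

When a `NetworkConfig` declares its intended `input_shape`, construction
fails if the large kernel exceeds the deepest encoder grid. Without a
declared shape any input divisible by `2^(n_levels−1)` is accepted: the
zero-padded convolution stays well defined even where the kernel overhangs
the volume, which is the normal situation for desk-scale inputs.

### Numerical engine

No deep-learning framework is used: the package carries a small tape-based
reverse-mode autodiff over numpy arrays. Depthwise 3D convolutions are
computed with real FFTs at size N + e − 1 per axis, which simultaneously
(a) makes the cost nearly independent of kernel edge — the point of
large-kernel design — and (b) keeps circular correlation alias-free for
every lag the kernel needs, so the input spectrum computed in the forward
pass is reused for both the input gradient (one circular convolution) and
the kernel gradient (one circular correlation). All custom vjps are verified
against central finite differences in the test suite. Float32 is used
throughout training; constants never promote the graph to float64.

## Postprocessing

Suppression acts on the foreground probability channel. The surface shell
is the brain mask minus a per-axis erosion by `round(thickness/spacing)`
voxels (default thickness 2 mm — a config item, as the choice is not
dictated by the method); the choroid mask comes from the phantom generator
(atlas registration for real data is out of scope). Two modes:

- `zero_probability` (default): zero the probability inside the masks, then
  threshold (0.5) and drop components smaller than `min_component_voxels`
  (default 2). This is the literal per-channel operation.
- `component_filter`: threshold first, then remove whole components whose
  in-mask voxel fraction reaches θ (default 0.5). Offered because zeroing
  can bisect a true lesion that touches the shell.

Both modes are monotone (never add foreground) and idempotent.

## Lesion-level evaluation

Components are 26-connected. A ground-truth lesion is detected iff it
overlaps the prediction by ≥ 1 voxel; each predicted component is assigned
to its maximum-overlap GT lesion (ties to the lower id) and is an FP if it
overlaps none. Sensitivity counts on the GT side and precision on the
prediction side, so split and merge cases remain well defined; the criterion
is deliberately the weakest (any-overlap), making it exactly checkable
against a voxel-set oracle. Size classes use the equivalent-sphere diameter
(6V/π)^(1/3) with the 10 mm boundary inclusive to "small"; FP components are
classed by their own diameter, predicted TPs by their matched GT lesion.
Per-lesion DSC scores each GT lesion against the union of its assigned
components (an undetected lesion scores 0) and is averaged overall and per
class; the global all-voxel DSC is reported separately. Volume agreement
pairs each GT lesion with its predicted volume (0 when missed; FPs excluded)
and reports Pearson's r plus Bland–Altman mean difference and
mean ± 1.96·sd limits (sample sd). Conventions: both-empty DSC = 1.0;
zero-variance volume lists report r as missing; zero GT lesions report
sensitivity as missing rather than 0.

## Response assessment

For a perfect sphere a fractional diameter increase δ multiplies volume by
(1+δ)³, so the unidimensional 20 % progression criterion maps to a
volumetric threshold of (1.2)³ − 1 = 72.8 %. Classification of a
baseline/follow-up pair over total solid volume V:

| condition | category |
|---|---|
| new lesion, or (V_f − V_b)/V_b ≥ 0.728 (boundary inclusive) | PD |
| V_f = 0 and no new lesion | CR |
| otherwise | PR/SD |

Lesions are linked across timepoints greedily by descending overlap, then by
centroid distance (≤ 10 mm default) for non-overlapping remnants; an
unmatched follow-up component counts as a new lesion only at
≥ `new_lesion_min_voxels` (default 2), so single-voxel noise cannot force
PD. A zero baseline volume is an error, not a silent classification.
Registration between timepoints is assumed done.

Rater agreement: 3×3 confusion matrix, percent agreement, and ICC(2,1) —
two-way random effects, absolute agreement, single rater — from the two-way
ANOVA decomposition with McGraw–Wong F-based 95 % bounds (verified against
an explicit sums-of-squares oracle and against pingouin's ICC(A,1)).
Categories are coded ordinally CR=1 < PR/SD=2 < PD=3 when fed to the ICC;
this coding is a package decision and is stated here because agreement
statistics on categories are coding-dependent.

## Synthetic phantoms

`PhantomSpec` defaults: 64³ voxels at 1 mm isotropic, 5 lesions with
diameters uniform in [4, 14] mm, necrosis probability 0.3 with core radius
half the lesion radius, 2–3 random-walk vessels of 1 mm radius, a central
choroid-like ellipsoid, intensities (background 0, brain 0.2, lesion rim
1.0, necrotic core 0.35, vessel 0.9, choroid 0.85) and Gaussian noise
σ = 0.05. Lesions are mildly anisotropic ellipsoids (axis factors in
[0.8, 1.25]) placed by rejection sampling with a 2-voxel clearance from each
other and the choroid, and a 3-voxel clearance from the brain surface so a
2 mm surface shell never clips a true lesion. All randomness flows from a
single generator seeded per call; generation is bit-deterministic.

What the phantoms emulate: the intensity ordering and morphology of BB
imaging (dark vessels *re-brightened* here deliberately, as the residual
unsuppressed segments are the FP source of interest), necrosis-excluding
ground truth, size mixture spanning the 10 mm boundary. What they do not:
MRI physics (no bias fields, partial volume, k-space artefacts), real lesion
texture, skull/meninges, or registration error between timepoints. Passing
the end-to-end tests therefore certifies the *machinery* — architecture,
gradients, fusion, suppression, matching, statistics — not clinical
performance.

Follow-up simulation for the response stage draws an outcome per patient
(CR 5 %, PR/SD 45 %, PD-by-growth 25 %, PD-by-new-lesion 25 %, roughly the
category mix seen in treated cohorts) and edits the baseline ground truth
accordingly (emptying, deleting one lesion, dilating until ≥ 80 % volume
growth, or adding a distant blob).

## Scaled-down study conditions

The end-to-end run used by the tests and the acceptance script is sized for
a single CPU: 12 synthetic patients, 3 stratified folds with one test fold
(8 train / 4 test), a 2-level 8-channel network with a 7³/3³ kernel pair,
200 Adam steps on 32³ lesion-biased patches of easy (high-contrast,
σ = 0.02) phantoms, whole-volume 64³ inference. Patch-based training (rather
than whole-volume) was adopted because it reaches the same quality in a
fraction of the arithmetic; patches are sampled with 70 % probability
centred on a lesion voxel. Under these conditions the pipeline reaches
sensitivity 1.0 and mean per-lesion DSC ≈ 0.85–0.95, and mask suppression
removes the large majority of raw FP components — comfortably clearing the
sensitivity ≥ 0.7 / DSC ≥ 0.5 acceptance bars while staying minutes-scale.

## Stratified splitting

Patients are assigned to K folds (default 5) balancing small/large lesion
counts: descending (large, small) order with a seeded tie shuffle, greedy
placement into the capacity-limited fold that minimises the deviation of the
fold's small-lesion count from its proportional share, followed by a
deterministic pairwise-swap refinement minimising the summed squared
deviation of per-fold small-lesion proportions. Validation patients
(fraction 0.10) are drawn at patient level from the training folds.

## Known limitations

- The numpy engine trains small networks on small volumes; it is not a
  GPU-scale trainer, and the full 4-level/13³ configuration is practical
  for inference and fusion checks rather than long training runs.
- The any-overlap detection criterion is generous; published lesion-level
  numbers often use stricter overlap fractions and are not directly
  comparable.
- CR requires exactly zero follow-up volume after postprocessing (the
  min-component filter makes this attainable); an "unequivocal enhancement"
  qualifier is not implementable on masks alone.
- Choroid-plexus masking for real data would need atlas registration, which
  is out of scope; phantoms use the generator's own mask.
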