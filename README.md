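# bmseg

Detection and segmentation of brain metastases on contrast-enhanced
black-blood T1-weighted MRI, with lesion-level evaluation and automated
volumetric treatment-response assessment — built as a fully testable pipeline
driven by synthetic 3D phantoms, so every stage can be exercised and verified
without any clinical data.

## Who this is for

Researchers developing or evaluating lesion-detection networks for brain
metastases (BMs), and anyone who needs the surrounding machinery: lesion-wise
detection metrics (sensitivity, precision, FP/scan), Dice overlap, volumetric
response classification in the RANO-BM spirit, and inter-rater agreement
statistics (ICC, percent agreement, Bland–Altman).

## What is inside

**Segmentation network.** A 4-level 3D U-Net whose encoder blocks run two
parallel *depthwise* convolution branches — a large kernel (13×13×13) for a
wide receptive field and a small parallel kernel (5×5×5) — each with its own
normalisation, summed and passed through GELU between pointwise
channel-mixing layers. After training, the branches are *re-parameterized*:
each normalisation is folded into its kernel
(`w' = w·γ/√(σ²+ε)`, `b' = β − μ·γ/√(σ²+ε)`), the small kernel is zero-padded
to the large edge, and the branches are summed into a single depthwise kernel
whose forward pass is numerically equivalent. The decoder upsamples with
trilinear interpolation and skip concatenation; multiscale highlighting of
foregrounds (MHF) is realised as deep supervision against max-pooled ground
truth at every coarse scale. The network, its training loop and the
reverse-mode gradient engine are implemented in numpy/scipy (FFT-based
depthwise convolutions, so very large kernels cost no more than small ones).

**Ground-truth convention.** Segmentations cover the solid enhancing rim
only: necrotic cores are excluded, both in the synthetic phantoms and in the
volumes the response classifier compares — non-enhancing cavities should not
be measured when scoring response.

**Postprocessing.** False-positive suppression on the foreground channel
with a brain-surface shell (incompletely suppressed vessels) and a
choroid-plexus mask, followed by binarization and small-component removal.

**Evaluation.** Connected-component lesion matching (any-overlap,
max-overlap assignment), sensitivity = TP/(TP+FN) on the ground-truth side,
precision = TP/(TP+FP) on the prediction side, FP/scan, missed lesions per
patient, size stratification at 10 mm equivalent-sphere diameter (boundary
inclusive to "small"), per-lesion and global DSC = 2|Vs∩Vg|/(|Vs|+|Vg|),
Pearson correlation and Bland–Altman limits of agreement on lesion volumes.

**Response assessment.** For co-registered baseline/follow-up segmentation
pairs: progressive disease (PD) iff a new lesion appears or total solid
volume grows by ≥ 72.8 % — the volumetric counterpart of a 20 % sphere
diameter increase, (1.2)³ − 1 = 0.728; complete response (CR) iff all volume
disappears; otherwise PR/SD. Agreement between two raters is summarised by a
3×3 confusion matrix, percent agreement, and ICC(2,1) (two-way random
effects, absolute agreement) with its 95 % CI.

**Phantoms.** Reproducible toy volumes emulating black-blood contrast:
dark background, mid-grey ellipsoidal brain, bright quasi-spherical lesions
(some with darker necrotic cores excluded from ground truth), bright
random-walk vessel tubes and a choroid-plexus-like blob as FP distractors,
plus Gaussian noise. Every mask and a lesion catalog are returned, so all
metrics have exact references.

## Worked example

```python
import bmseg as B

report = B.run_pipeline(B.RunConfig(seed=1, with_response_stage=True))
p = report["pooled"]
print(f"sensitivity {p['sensitivity']:.2f}  precision {p['precision']:.2f}  "
      f"mean DSC {p['mean_dsc']:.2f}")
print(f"FP/scan {p['fp_per_scan_unsuppressed']:.2f} -> {p['fp_per_scan']:.2f} "
      f"after mask suppression")
r = report["response"]
print(f"response agreement {r['percent_agreement']:.1f}%  ICC {r['icc_2_1']:.2f}")
```

prints (one CPU, ~1 minute):

```
sensitivity 1.00  precision 0.92  mean DSC 0.87
FP/scan 3.50 -> 0.25 after mask suppression
response agreement 100.0%  ICC 1.00
```

That run generates a 12-patient synthetic cohort, splits it into 3
size-stratified folds, trains a scaled-down network (2 levels, 8 base
channels, 7/3-voxel kernel pair) for 200 steps on the 8 training patients,
predicts the 4 held-out patients, suppresses FPs with the surface/choroid/
vessel masks, pools lesion metrics, then simulates follow-up scans and
compares the volumetric response classification against the constructed
outcomes. The suppression line shows the point of the mask step: vessel and
choroid mimics dominate the raw false positives and are removed without
touching true lesions.

The same stages are scriptable from the shell:

```bash
bmseg phantom --seed 1 --out ph/
bmseg train --config run.yaml --seed 1 --out run/
bmseg predict --checkpoint run/checkpoint.npz --in ph/intensity.nii.gz --out prob.nii.gz --fused
bmseg postprocess --prob prob.nii.gz --brain ph/brain_mask.nii.gz --choroid ph/choroid_mask.nii.gz --out pred.nii.gz
bmseg evaluate --gt ph/gt_mask.nii.gz --pred pred.nii.gz --report metrics.json
```

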