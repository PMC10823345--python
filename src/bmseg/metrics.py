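"""Lesion-level detection and segmentation evaluation.

Detection is scored on connected components, not voxels: a ground-truth (GT)
lesion counts as detected (TP) iff it overlaps the prediction by at least
``min_overlap_voxels``; each predicted component is assigned to the GT lesion
it overlaps most (ties to the lower GT id) and is a false positive if it
overlaps none. Sensitivity is counted on the GT side, precision on the
prediction side, so split/merge cases stay well defined. Lesions are
stratified at an equivalent-sphere diameter of 10 mm (boundary inclusive to
"small"). Segmentation quality is the Dice similarity coefficient
DSC = 2|A∩B| / (|A|+|B|), and volumetric agreement between matched GT and
predicted lesions is summarised by Pearson's r and Bland–Altman limits of
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

from .phantom import equivalent_diameter_mm, size_class_of

CONNECTIVITY_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)
CONNECTIVITY_STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class ComponentSet:
    """Connected components of one binary mask with per-component metadata."""

    labels: np.ndarray  # int grid, 0 = background, ids dense from 1
    n_components: int
    voxel_counts: np.ndarray  # (n,) voxels per component (index id-1)
    volumes_mm3: np.ndarray
    centroids_mm: np.ndarray  # (n, 3)
    equivalent_diameters_mm: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def size_classes(self) -> list[str]:
        return [size_class_of(d) for d in self.equivalent_diameters_mm]


@dataclass
class MatchResult:
    """GT <-> prediction component matching for one scan."""

    matches: list[tuple[int, int, int]]  # (gt_id, pred_id, overlap_voxels)
    tp_gt: list[int]
    fn: list[int]
    tp_pred: list[int]
    fp: list[int]


@dataclass
class ClassCounts:
    tp_gt: int = 0
    fn: int = 0
    tp_pred: int = 0
    fp: int = 0

    @property
    def sensitivity(self) -> float | None:
        n = self.tp_gt + self.fn
        return self.tp_gt / n if n else None

    @property
    def precision(self) -> float | None:
        n = self.tp_pred + self.fp
        return self.tp_pred / n if n else None


@dataclass
class DetectionMetrics:
    sensitivity: float | None
    precision: float | None
    fp_per_scan: float
    missed_bm_per_patient: float
    n_scans: int
    n_patients: int
    by_class: dict[str, ClassCounts] = field(default_factory=dict)

    def class_sensitivity(self, cls: str) -> float | None:
        return self.by_class[cls].sensitivity

    def class_precision(self, cls: str) -> float | None:
        return self.by_class[cls].precision


@dataclass
class SegmentationMetrics:
    per_lesion_dsc: list[float]
    per_lesion_class: list[str]
    mean_dsc: float | None
    mean_dsc_by_class: dict[str, float | None]
    global_dsc: float


@dataclass
class VolumeAgreement:
    pearson_r: float | None
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int


def label_components(
    mask: np.ndarray, spacing: Sequence[float], connectivity: int = 26
) -> ComponentSet:
    """Connected components of a binary mask (26- or 6-neighbourhood)."""
    arr = np.asarray(mask)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask must be binary, found values {uniq[:10]}")
    if connectivity == 26:
        structure = CONNECTIVITY_STRUCTURE_26
    elif connectivity == 6:
        structure = CONNECTIVITY_STRUCTURE_6
    else:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    spacing = tuple(float(s) for s in spacing)
    labels, n = ndimage.label(arr.astype(bool), structure=structure)
    if n == 0:
        return ComponentSet(
            labels=labels,
            n_components=0,
            voxel_counts=np.zeros(0, dtype=int),
            volumes_mm3=np.zeros(0),
            centroids_mm=np.zeros((0, 3)),
            equivalent_diameters_mm=np.zeros(0),
            spacing=spacing,
        )
    ids = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    voxel_vol = spacing[0] * spacing[1] * spacing[2]
    volumes = counts * voxel_vol
    centroids_vox = np.array(ndimage.center_of_mass(arr.astype(bool), labels, ids))
    centroids_mm = centroids_vox * np.asarray(spacing)
    diameters = np.array([equivalent_diameter_mm(v) for v in volumes])
    return ComponentSet(
        labels=labels,
        n_components=n,
        voxel_counts=counts,
        volumes_mm3=volumes,
        centroids_mm=centroids_mm,
        equivalent_diameters_mm=diameters,
        spacing=spacing,
    )


def overlap_matrix(gt: ComponentSet, pred: ComponentSet) -> np.ndarray:
    """(n_gt, n_pred) matrix of pairwise overlap voxel counts."""
    if gt.labels.shape != pred.labels.shape:
        raise ValueError(
            f"grids differ: {gt.labels.shape} vs {pred.labels.shape}"
        )
    ng, np_ = gt.n_components, pred.n_components
    if ng == 0 or np_ == 0:
        return np.zeros((ng, np_), dtype=int)
    both = (gt.labels > 0) & (pred.labels > 0)
    pair = gt.labels[both].astype(np.int64) * (np_ + 1) + pred.labels[both]
    counts = np.bincount(pair, minlength=(ng + 1) * (np_ + 1))
    return counts.reshape(ng + 1, np_ + 1)[1:, 1:]


def match_lesions(
    gt: ComponentSet, pred: ComponentSet, min_overlap_voxels: int = 1
) -> MatchResult:
    """Any-overlap detection matching with max-overlap assignment."""
    if min_overlap_voxels < 1:
        raise ValueError("min_overlap_voxels must be >= 1")
    ov = overlap_matrix(gt, pred)
    matches: list[tuple[int, int, int]] = []
    tp_pred, fp = [], []
    for j in range(pred.n_components):
        col = ov[:, j]
        if gt.n_components and col.max() >= min_overlap_voxels:
            gt_idx = int(np.argmax(col))  # argmax takes the lowest id on ties
            matches.append((gt_idx + 1, j + 1, int(col[gt_idx])))
            tp_pred.append(j + 1)
        else:
            fp.append(j + 1)
    qualifying = (
        (ov >= min_overlap_voxels).any(axis=1)
        if pred.n_components
        else np.zeros(gt.n_components, dtype=bool)
    )
    tp_gt = [i + 1 for i in range(gt.n_components) if qualifying[i]]
    fn = [i + 1 for i in range(gt.n_components) if not qualifying[i]]
    return MatchResult(matches=matches, tp_gt=tp_gt, fn=fn, tp_pred=tp_pred, fp=fp)


def detection_metrics(
    match_results: Sequence[MatchResult],
    gt_sets: Sequence[ComponentSet],
    pred_sets: Sequence[ComponentSet],
    n_patients: int | None = None,
) -> DetectionMetrics:
    """Pool per-scan match results into cohort-level detection metrics.

    GT lesions are size-classed by their own equivalent diameter; a predicted
    TP inherits the class of its matched GT lesion; an FP is classed by its
    own diameter. With zero GT lesions overall, sensitivity is reported as
    missing (None), never as 0.
    """
    if not match_results:
        raise ValueError("need at least one scan")
    if not (len(match_results) == len(gt_sets) == len(pred_sets)):
        raise ValueError("match_results, gt_sets and pred_sets must align")
    n_scans = len(match_results)
    n_patients = n_patients or n_scans
    total = ClassCounts()
    by_class = {"small": ClassCounts(), "large": ClassCounts()}
    for mr, gt, pred in zip(match_results, gt_sets, pred_sets):
        gt_cls = gt.size_classes
        pred_cls = pred.size_classes
        matched_gt_of_pred = {p: g for g, p, _ in mr.matches}
        for gid in mr.tp_gt:
            by_class[gt_cls[gid - 1]].tp_gt += 1
            total.tp_gt += 1
        for gid in mr.fn:
            by_class[gt_cls[gid - 1]].fn += 1
            total.fn += 1
        for pid in mr.tp_pred:
            cls = gt_cls[matched_gt_of_pred[pid] - 1]
            by_class[cls].tp_pred += 1
            total.tp_pred += 1
        for pid in mr.fp:
            by_class[pred_cls[pid - 1]].fp += 1
            total.fp += 1
    return DetectionMetrics(
        sensitivity=total.sensitivity,
        precision=total.precision,
        fp_per_scan=total.fp / n_scans,
        missed_bm_per_patient=total.fn / n_patients,
        n_scans=n_scans,
        n_patients=n_patients,
        by_class=by_class,
    )


def dsc(seg_a: np.ndarray, seg_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); both-empty -> 1.0."""
    a = np.asarray(seg_a).astype(bool)
    b = np.asarray(seg_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0  # both-empty convention
    return 2.0 * int((a & b).sum()) / (na + nb)


def segmentation_metrics(
    gt: ComponentSet, pred: ComponentSet, match: MatchResult
) -> SegmentationMetrics:
    """Per-lesion DSC (each GT lesion against the union of its assigned
    predicted components; unmatched GT lesions score 0), class means, and the
    global all-voxel DSC."""
    pred_of_gt: dict[int, list[int]] = {}
    for g, p, _ in match.matches:
        pred_of_gt.setdefault(g, []).append(p)
    per_dsc, per_cls = [], []
    classes = gt.size_classes
    for gid in range(1, gt.n_components + 1):
        gmask = gt.labels == gid
        pids = pred_of_gt.get(gid, [])
        pmask = np.isin(pred.labels, pids) if pids else np.zeros_like(gmask)
        per_dsc.append(dsc(gmask, pmask))
        per_cls.append(classes[gid - 1])
    def mean_or_none(values):
        return float(np.mean(values)) if values else None

    by_class = {
        cls: mean_or_none([d for d, c in zip(per_dsc, per_cls) if c == cls])
        for cls in ("small", "large")
    }
    return SegmentationMetrics(
        per_lesion_dsc=per_dsc,
        per_lesion_class=per_cls,
        mean_dsc=mean_or_none(per_dsc),
        mean_dsc_by_class=by_class,
        global_dsc=dsc(gt.labels > 0, pred.labels > 0),
    )


def matched_volume_pairs(
    gt: ComponentSet, pred: ComponentSet, match: MatchResult
) -> list[tuple[float, float]]:
    """Per-GT-lesion (gt_volume, predicted_volume) pairs in mm^3.

    The predicted volume of a GT lesion sums its assigned components; an
    undetected lesion pairs with 0. FP components contribute no pair.
    """
    pred_vol_of_gt = {g: 0.0 for g in range(1, gt.n_components + 1)}
    for g, p, _ in match.matches:
        pred_vol_of_gt[g] += float(pred.volumes_mm3[p - 1])
    return [
        (float(gt.volumes_mm3[g - 1]), pred_vol_of_gt[g])
        for g in range(1, gt.n_components + 1)
    ]


def volume_agreement(
    gt_volumes: Sequence[float], pred_volumes: Sequence[float]
) -> VolumeAgreement:
    """Pearson correlation and Bland–Altman limits for paired volumes.

    Differences are predicted - ground truth; limits of agreement are
    mean ± 1.96 * sd with the sample (n-1) standard deviation. With zero
    variance in either list, r is reported missing.
    """
    g = np.asarray(gt_volumes, dtype=float)
    p = np.asarray(pred_volumes, dtype=float)
    if g.shape != p.shape or g.ndim != 1:
        raise ValueError("volume lists must be paired 1-D sequences")
    if g.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(g) == 0 or np.std(p) == 0:
        r = None
    else:
        r = float(sstats.pearsonr(g, p).statistic)
    diff = p - g
    mean_d = float(diff.mean())
    sd_d = float(diff.std(ddof=1))
    return VolumeAgreement(
        pearson_r=r,
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        n=g.size,
    )
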