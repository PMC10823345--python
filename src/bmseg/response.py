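"""Volumetric treatment-response assessment and rater agreement.

The response of brain metastases to therapy is classified from paired
baseline/follow-up segmentations using a volumetric adaptation of the
RANO-BM categories. The unidimensional criterion for progressive disease
(>= 20% diameter increase) maps, for a perfect sphere, to a >= 72.8% volume
increase ((1.2)^3 - 1); progression is therefore declared when total solid
enhancing volume grows by at least that fraction, or when a new lesion
appears. Complete response requires total disappearance with no new lesion;
everything else is partial response / stable disease. Necrotic cores are
already excluded by the segmentation convention, so the volumes compared
here are solid enhancing tumour only.

Agreement between two raters (e.g. radiologist vs algorithm) is summarised
by a 3x3 confusion matrix, percent agreement, and the intraclass correlation
ICC(2,1) — two-way random effects, absolute agreement, single rater — with
its 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .metrics import ComponentSet, overlap_matrix

CATEGORIES = ("CR", "PR_SD", "PD")
# Ordinal numeric coding used when feeding categories to the ICC.
CATEGORY_CODES = {"CR": 1, "PR_SD": 2, "PD": 3}


@dataclass
class ResponseConfig:
    pd_volume_increase_threshold: float = 0.728
    new_lesion_min_voxels: int = 2
    correspondence_max_centroid_distance_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.pd_volume_increase_threshold <= 0:
            raise ValueError("PD threshold must be positive")
        if self.new_lesion_min_voxels < 1:
            raise ValueError("new_lesion_min_voxels must be >= 1")


@dataclass
class TimepointPair:
    baseline: ComponentSet
    followup: ComponentSet

    def __post_init__(self) -> None:
        if self.baseline.labels.shape != self.followup.labels.shape:
            raise ValueError("baseline and follow-up grids must match")
        if self.baseline.spacing != self.followup.spacing:
            raise ValueError("baseline and follow-up spacing must match")


@dataclass
class CorrespondenceMap:
    links: list[tuple[int, int]]  # (baseline_id, followup_id), one-to-one
    resolved: list[int]  # baseline ids with no follow-up counterpart
    new_lesions: list[int]  # follow-up ids with no baseline counterpart, >= min voxels
    sub_threshold: list[int]  # unmatched follow-up ids below the new-lesion size


@dataclass
class ResponseResult:
    category: str  # CR | PR_SD | PD
    reasons: list[str]
    baseline_volume_mm3: float
    followup_volume_mm3: float
    relative_change: float

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "reasons": self.reasons,
            "baseline_volume_mm3": self.baseline_volume_mm3,
            "followup_volume_mm3": self.followup_volume_mm3,
            "relative_change": self.relative_change,
        }


@dataclass
class AgreementStats:
    icc: float | None
    icc_ci95: tuple[float, float] | None
    percent_agreement: float
    confusion: np.ndarray  # 3x3, rows = rater A, cols = rater B
    n: int


def diameter_to_volume_ratio(delta: float) -> float:
    """Fractional volume increase of a sphere whose diameter grows by ``delta``.

    (1 + delta)^3 - 1: a 20% diameter increase corresponds to a 72.8%
    volume increase.
    """
    if delta <= -1:
        raise ValueError("diameter change must exceed -100%")
    return (1.0 + delta) ** 3 - 1.0


def volume_to_diameter_ratio(ratio: float) -> float:
    """Inverse of :func:`diameter_to_volume_ratio`."""
    if ratio <= -1:
        raise ValueError("volume change must exceed -100%")
    return (1.0 + ratio) ** (1.0 / 3.0) - 1.0


def correspond_lesions(pair: TimepointPair, cfg: ResponseConfig) -> CorrespondenceMap:
    """One-to-one lesion linking across timepoints (grids assumed co-registered).

    Links are made greedily by descending spatial overlap; remaining
    candidates may link by centroid distance up to
    ``correspondence_max_centroid_distance_mm``. Unlinked baseline lesions are
    resolved; unlinked follow-up components are new lesions if they reach
    ``new_lesion_min_voxels``, otherwise sub-threshold noise.
    """
    base, fup = pair.baseline, pair.followup
    ov = overlap_matrix(base, fup)
    links: list[tuple[int, int]] = []
    used_b: set[int] = set()
    used_f: set[int] = set()
    if ov.size:
        order = np.argsort(ov, axis=None)[::-1]
        for flat in order:
            i, j = np.unravel_index(flat, ov.shape)
            if ov[i, j] < 1:
                break
            if (i + 1) in used_b or (j + 1) in used_f:
                continue
            links.append((i + 1, j + 1))
            used_b.add(i + 1)
            used_f.add(j + 1)
    # distance-based pass for non-overlapping pairs
    candidates = []
    for i in range(base.n_components):
        if (i + 1) in used_b:
            continue
        for j in range(fup.n_components):
            if (j + 1) in used_f:
                continue
            d = float(np.linalg.norm(base.centroids_mm[i] - fup.centroids_mm[j]))
            if d <= cfg.correspondence_max_centroid_distance_mm:
                candidates.append((d, i + 1, j + 1))
    for d, bi, fj in sorted(candidates):
        if bi in used_b or fj in used_f:
            continue
        links.append((bi, fj))
        used_b.add(bi)
        used_f.add(fj)
    resolved = [i for i in range(1, base.n_components + 1) if i not in used_b]
    new_lesions, sub_threshold = [], []
    for j in range(1, fup.n_components + 1):
        if j in used_f:
            continue
        if fup.voxel_counts[j - 1] >= cfg.new_lesion_min_voxels:
            new_lesions.append(j)
        else:
            sub_threshold.append(j)
    return CorrespondenceMap(
        links=links,
        resolved=resolved,
        new_lesions=new_lesions,
        sub_threshold=sub_threshold,
    )


def classify_response(
    pair: TimepointPair,
    correspondence: CorrespondenceMap,
    cfg: ResponseConfig,
) -> ResponseResult:
    """Apply the volumetric response rule to one baseline/follow-up pair.

    PD iff a new lesion appeared or total solid volume grew by at least the
    threshold (boundary inclusive); else CR iff follow-up volume is exactly
    zero; else PR_SD. Baseline volume must be positive — a patient with no
    baseline disease needs new-lesion-only handling by the caller.
    """
    v_base = float(pair.baseline.volumes_mm3.sum())
    v_fup = float(pair.followup.volumes_mm3.sum())
    if v_base <= 0:
        raise ValueError(
            "baseline volume is zero: the relative-change rule is undefined; "
            "assess this case on new lesions alone"
        )
    rel = (v_fup - v_base) / v_base
    reasons: list[str] = []
    if correspondence.new_lesions:
        reasons.append("new_lesion")
    if rel >= cfg.pd_volume_increase_threshold:
        reasons.append("volume_increase_ge_threshold")
    if reasons:
        category = "PD"
    elif v_fup == 0.0:
        category = "CR"
        reasons = ["total_disappearance"]
    else:
        category = "PR_SD"
        reasons = ["neither"]
    return ResponseResult(
        category=category,
        reasons=reasons,
        baseline_volume_mm3=v_base,
        followup_volume_mm3=v_fup,
        relative_change=rel,
    )


def confusion_and_agreement(
    ratings_a: Sequence[str], ratings_b: Sequence[str]
) -> AgreementStats:
    """3x3 confusion matrix (rows = rater A) and percent agreement."""
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating lists must have equal length")
    if not ratings_a:
        raise ValueError("need at least one rating pair")
    idx = {c: i for i, c in enumerate(CATEGORIES)}
    confusion = np.zeros((3, 3), dtype=int)
    for a, b in zip(ratings_a, ratings_b):
        if a not in idx or b not in idx:
            raise ValueError(f"unknown category in pair ({a!r}, {b!r})")
        confusion[idx[a], idx[b]] += 1
    n = len(ratings_a)
    agreement = 100.0 * np.trace(confusion) / n
    return AgreementStats(
        icc=None,
        icc_ci95=None,
        percent_agreement=agreement,
        confusion=confusion,
        n=n,
    )


def icc_2_1(
    ratings: np.ndarray, alpha: float = 0.05
) -> tuple[float | None, tuple[float, float] | None]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is (n subjects x k raters) with no missing cells. Returns
    (icc, (ci_low, ci_high)). The point estimate is
    (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) from the two-way
    ANOVA decomposition, the CI follows the F-based large-sample formulas.
    Degenerate cases: perfect agreement with subject variance -> (1.0, (1, 1));
    all ratings identical (no subject variance) -> (None, None).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (n >= 2 subjects) x (k >= 2 raters)")
    if np.isnan(x).any():
        raise ValueError("ratings must have no missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 0 and mse <= 0:
        return None, None  # no variance anywhere: agreement undefined
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if mse <= 1e-30 and msc <= 1e-30:
        return 1.0, (1.0, 1.0)  # exact agreement
    icc = (msr - mse) / denom

    # McGraw & Wong confidence bounds for ICC(A,1)
    if icc >= 1.0:
        return float(icc), (1.0, 1.0)
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_low = sstats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = sstats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (
        n * (msr - f_low * mse)
        / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    upper = (
        n * (f_up * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    )
    return float(icc), (float(lower), float(upper))


def agreement_stats(
    ratings_a: Sequence[str], ratings_b: Sequence[str]
) -> AgreementStats:
    """Full agreement summary between two categorical raters: confusion,
    percent agreement, and ICC(2,1) under ordinal CR=1 < PR_SD=2 < PD=3
    coding."""
    stats = confusion_and_agreement(ratings_a, ratings_b)
    coded = np.array(
        [
            [CATEGORY_CODES[a] for a in ratings_a],
            [CATEGORY_CODES[b] for b in ratings_b],
        ]
    ).T
    icc, ci = icc_2_1(coded)
    stats.icc = icc
    stats.icc_ci95 = ci
    return stats
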