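"""Experiment orchestration: stratified splitting, training, full pipeline.

One "patient" is one synthetic phantom. Patients are split into K folds with
a greedy stratified assignment that balances small (<= 10 mm) and large
(> 10 mm) lesion counts across folds, training runs on K-1 folds with a
patient-level validation hold-out, and evaluation pools lesion-level metrics
over the test folds. A follow-up simulator derives paired timepoints from a
baseline phantom so the volumetric response classifier and the rater
agreement statistics can be exercised end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .metrics import (
    ComponentSet,
    detection_metrics,
    label_components,
    match_lesions,
    matched_volume_pairs,
    segmentation_metrics,
    volume_agreement,
)
from .network import (
    Network,
    NetworkConfig,
    build_network,
    composite_loss,
    mhf_targets,
)
from .phantom import PhantomSpec, PhantomVolume, generate_phantom
from .postprocess import BinarizationConfig, SuppressionMasks, make_surface_shell, suppress
from .response import (
    ResponseConfig,
    TimepointPair,
    agreement_stats,
    classify_response,
    correspond_lesions,
)

logger = logging.getLogger("bmseg")


# ---------------------------------------------------------------------------
# Stratified K-fold


@dataclass
class FoldSpec:
    k: int
    assignments: dict[int, int]  # patient_id -> fold index
    fold_strata: list[tuple[int, int]]  # per fold: (small count, large count)
    validation_fraction: float
    seed: int

    def patients_in_fold(self, fold: int) -> list[int]:
        return sorted(p for p, f in self.assignments.items() if f == fold)

    def training_patients(self, test_fold: int) -> list[int]:
        return sorted(p for p, f in self.assignments.items() if f != test_fold)


def stratified_kfold(
    patient_strata: dict[int, tuple[int, int]], k: int = 5, seed: int = 0
) -> FoldSpec:
    """Greedy stratified assignment of patients to K folds.

    ``patient_strata`` maps patient id to (small lesion count, large lesion
    count). Patients are processed in descending (large, small) order with a
    seeded shuffle among ties; each goes to the fold (among those with
    remaining patient capacity, so fold sizes stay balanced and nonempty)
    whose resulting small:large proportion deviates least from the global
    proportion. Deterministic under ``seed``.
    """
    if len(patient_strata) < k:
        raise ValueError(
            f"need at least k={k} patients, got {len(patient_strata)}"
        )
    rng = np.random.default_rng(seed)
    ids = list(patient_strata)
    rng.shuffle(ids)
    ids.sort(
        key=lambda p: (patient_strata[p][1], patient_strata[p][0]), reverse=True
    )
    n = len(ids)
    capacity = [n // k + (1 if f < n % k else 0) for f in range(k)]
    totals = np.array([patient_strata[p] for p in ids], dtype=float).sum(axis=0)
    global_prop = totals[0] / totals.sum() if totals.sum() else 0.0
    fold_totals = np.zeros((k, 2))
    fold_counts = [0] * k
    assignments: dict[int, int] = {}
    for p in ids:
        s, l = patient_strata[p]
        best, best_key = None, None
        for f in range(k):
            if fold_counts[f] >= capacity[f]:
                continue
            ns, nl = fold_totals[f] + (s, l)
            # deviation of the fold's small count from its proportional share
            key = (abs(ns - global_prop * (ns + nl)), fold_counts[f], f)
            if best_key is None or key < best_key:
                best, best_key = f, key
        assignments[p] = best
        fold_totals[best] += (s, l)
        fold_counts[best] += 1

    def objective() -> float:
        dev = 0.0
        for f in range(k):
            tot = fold_totals[f].sum()
            if tot:
                dev += (fold_totals[f][0] / tot - global_prop) ** 2
        return dev

    # deterministic pairwise-swap refinement (fold sizes preserved)
    improved = True
    while improved:
        improved = False
        current = objective()
        for pa in ids:
            for pb in ids:
                fa, fb = assignments[pa], assignments[pb]
                if fa >= fb:
                    continue
                da = np.array(patient_strata[pa], float)
                db = np.array(patient_strata[pb], float)
                fold_totals[fa] += db - da
                fold_totals[fb] += da - db
                if objective() < current - 1e-12:
                    assignments[pa], assignments[pb] = fb, fa
                    improved = True
                    current = objective()
                else:
                    fold_totals[fa] -= db - da
                    fold_totals[fb] -= da - db
    strata = [tuple(int(x) for x in fold_totals[f]) for f in range(k)]
    return FoldSpec(
        k=k,
        assignments=assignments,
        fold_strata=strata,
        validation_fraction=0.10,
        seed=seed,
    )


def patient_strata_from_catalog(phantom: PhantomVolume) -> tuple[int, int]:
    small = sum(1 for r in phantom.catalog if r.size_class == "small")
    large = sum(1 for r in phantom.catalog if r.size_class == "large")
    return small, large


# ---------------------------------------------------------------------------
# Run configuration


def easy_phantom_spec(seed: int = 0, grid: int = 64) -> PhantomSpec:
    """High-contrast, low-noise phantom: the scaled-down study condition used
    for desk-scale training runs. Lesion diameters scale with the grid so
    smaller grids stay placeable."""
    scale = grid / 64.0
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        n_lesions=3,
        lesion_diameter_range=(max(3.0, 6.0 * scale), max(5.0, 14.0 * scale)),
        necrosis_probability=0.25,
        choroid_center_voxel=(int(0.35 * grid), grid // 2, grid // 2),
        choroid_semiaxes_mm=(6.0 * scale, 4.0 * scale, 4.0 * scale),
        n_vessels=2,
        noise_sigma=0.02,
        seed=seed,
    )


def tiny_network_config() -> NetworkConfig:
    """Two-level, 8-channel network with a 7/3 kernel pair: the scaled-down
    counterpart of the full 4-level 16-channel 13/5 architecture."""
    return NetworkConfig(
        n_levels=2,
        base_channels=8,
        large_kernel_edge=7,
        parallel_kernel_edge=3,
    )


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    phantom_spec: PhantomSpec = field(default_factory=easy_phantom_spec)
    network: NetworkConfig = field(default_factory=tiny_network_config)
    binarization: BinarizationConfig = field(default_factory=BinarizationConfig)
    response: ResponseConfig = field(default_factory=ResponseConfig)
    shell_thickness_mm: float = 2.0
    n_patients: int = 12
    k_folds: int = 3
    single_fold: bool = True  # evaluate fold 0 only (scaled-down default)
    predictor: str = "network"  # or "oracle" (predictions := ground truth)
    training_steps: int = 200
    learning_rate: float = 1e-3
    patch_size: int = 32
    validation_fraction: float = 0.10
    with_response_stage: bool = False
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom_spec"] = self.phantom_spec.to_dict()
        d["network"] = self.network.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["phantom_spec"] = PhantomSpec.from_dict(d["phantom_spec"])
        d["network"] = NetworkConfig.from_dict(d["network"])
        d["binarization"] = BinarizationConfig(**d["binarization"])
        d["response"] = ResponseConfig(**d["response"])
        return cls(**d)


def _sub_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic stage sub-seed, kept below 2^31."""
    h = int(seed) & 0xFFFFFFFF
    for ch in f"{stage}:{index}":
        h = (h * 31 + ord(ch)) & 0xFFFFFFFF
    return h % (2**31 - 1)


def generate_cohort(config: RunConfig) -> dict[int, PhantomVolume]:
    """One phantom per patient, each with its own derived seed."""
    cohort = {}
    for pid in range(config.n_patients):
        spec = dataclasses.replace(
            config.phantom_spec, seed=_sub_seed(config.seed, "phantom", pid)
        )
        cohort[pid] = generate_phantom(spec)
    return cohort


# ---------------------------------------------------------------------------
# Training


def _sample_patch(
    phantom: PhantomVolume, patch: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """A patch-sized crop, biased toward lesion-containing regions."""
    shape = phantom.intensity.shape
    gt_idx = np.argwhere(phantom.gt_mask)
    if len(gt_idx) and rng.random() < 0.7:
        center = gt_idx[rng.integers(len(gt_idx))]
        start = [
            int(np.clip(c - patch // 2 + rng.integers(-4, 5), 0, s - patch))
            for c, s in zip(center, shape)
        ]
    else:
        start = [int(rng.integers(0, s - patch + 1)) for s in shape]
    sl = tuple(slice(a, a + patch) for a in start)
    return phantom.intensity[sl], phantom.gt_mask[sl]


def train_network(
    net: Network,
    phantoms: Sequence[PhantomVolume],
    steps: int,
    learning_rate: float = 1e-3,
    patch_size: int = 32,
    seed: int = 0,
    log_every: int = 25,
) -> list[dict]:
    """Patch-based optimisation of the composite loss; returns the step log.

    Aborts with a diagnostic on divergence (non-finite loss).
    """
    rng = np.random.default_rng(seed)
    opt = ad.Adam(net.parameters(), lr=learning_rate)
    n_scales = net.config.n_levels - 1
    history: list[dict] = []
    for step in range(steps):
        phantom = phantoms[int(rng.integers(len(phantoms)))]
        vol, gt = _sample_patch(phantom, patch_size, rng)
        out = net.forward(vol, training_mode=True)
        targets = mhf_targets(gt, n_scales) if net.config.mhf_enabled else None
        loss = composite_loss(
            out, gt, aux_targets=targets, aux_loss_decay=net.config.aux_loss_decay
        )
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"training diverged at step {step}: loss={value}; "
                "reduce the learning rate or check the input scaling"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append({"step": step, "loss": value})
        if log_every and step % log_every == 0:
            logger.info("step %d loss %.4f", step, value)
    return history


def run_training(
    config: RunConfig,
    phantoms: dict[int, PhantomVolume] | None = None,
    training_patients: Sequence[int] | None = None,
) -> tuple[Network, list[dict], list[int]]:
    """Train a network per the run config; a patient-level fraction of the
    training set is held out for validation. Returns (net, history,
    validation patient ids)."""
    if phantoms is None:
        phantoms = generate_cohort(config)
    if training_patients is None:
        training_patients = sorted(phantoms)
    rng = np.random.default_rng(_sub_seed(config.seed, "valsplit"))
    ids = list(training_patients)
    rng.shuffle(ids)
    n_val = int(round(config.validation_fraction * len(ids)))
    n_val = min(n_val, max(len(ids) - 1, 0))
    val_ids = sorted(ids[:n_val])
    train_ids = sorted(ids[n_val:])
    net = build_network(config.network, seed=_sub_seed(config.seed, "init"))
    history = train_network(
        net,
        [phantoms[i] for i in train_ids],
        steps=config.training_steps,
        learning_rate=config.learning_rate,
        patch_size=config.patch_size,
        seed=_sub_seed(config.seed, "train"),
    )
    if val_ids and config.training_steps > 0:
        val_losses = []
        for pid in val_ids:
            ph = phantoms[pid]
            with ad.no_grad():
                out = net.forward(ph.intensity, training_mode=False)
                loss = composite_loss(out, ph.gt_mask)
            val_losses.append(float(loss.data))
        history.append(
            {"step": config.training_steps, "validation_loss": float(np.mean(val_losses))}
        )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        net.save(out / "checkpoint.npz")
        with open(out / "training_log.json", "w") as fh:
            json.dump(history, fh, indent=2)
    return net, history, val_ids


# ---------------------------------------------------------------------------
# Prediction + evaluation on one phantom


def predict_phantom(
    net: Network | None,
    phantom: PhantomVolume,
    binarization: BinarizationConfig,
    shell_thickness_mm: float = 2.0,
    oracle: bool = False,
    use_vessel_mask: bool = True,
    return_raw: bool = False,
):
    """Foreground probabilities -> suppression -> binary prediction.

    With ``return_raw`` also returns the plainly thresholded prediction
    (no suppression masks, no size filter) for before/after comparisons.
    """
    if oracle:
        prob = phantom.gt_mask.astype(np.float32)
    else:
        prob = net.predict_foreground(phantom.intensity)
    shell = make_surface_shell(
        phantom.brain_mask, shell_thickness_mm, phantom.spacing
    )
    masks = SuppressionMasks(
        surface_shell=shell,
        choroid_mask=phantom.choroid_mask,
        vessel_mask=phantom.vessel_mask if use_vessel_mask else None,
        shell_thickness_mm=shell_thickness_mm,
    )
    suppressed = suppress(prob, masks, binarization)
    if return_raw:
        return suppressed, prob > binarization.probability_threshold
    return suppressed


def evaluate_fold(
    phantoms: Sequence[PhantomVolume],
    predictions: Sequence[np.ndarray],
) -> dict:
    """Lesion metrics for one set of (phantom, binary prediction) pairs."""
    matches, gt_sets, pred_sets = [], [], []
    dsc_all, vol_gt, vol_pred = [], [], []
    for ph, pred in zip(phantoms, predictions):
        gt_cs = label_components(ph.gt_mask.astype(np.uint8), ph.spacing)
        pr_cs = label_components(pred.astype(np.uint8), ph.spacing)
        mr = match_lesions(gt_cs, pr_cs)
        matches.append(mr)
        gt_sets.append(gt_cs)
        pred_sets.append(pr_cs)
        seg = segmentation_metrics(gt_cs, pr_cs, mr)
        dsc_all.extend(seg.per_lesion_dsc)
        for g, p in matched_volume_pairs(gt_cs, pr_cs, mr):
            vol_gt.append(g)
            vol_pred.append(p)
    det = detection_metrics(matches, gt_sets, pred_sets)
    report = {
        "n_scans": det.n_scans,
        "sensitivity": det.sensitivity,
        "precision": det.precision,
        "fp_per_scan": det.fp_per_scan,
        "missed_bm_per_patient": det.missed_bm_per_patient,
        "sensitivity_small": det.class_sensitivity("small"),
        "sensitivity_large": det.class_sensitivity("large"),
        "mean_dsc": float(np.mean(dsc_all)) if dsc_all else None,
    }
    if len(vol_gt) >= 3:
        try:
            va = volume_agreement(vol_gt, vol_pred)
            report["volume_pearson_r"] = va.pearson_r
            report["volume_mean_difference_mm3"] = va.mean_difference
        except ValueError:
            pass
    return report


# ---------------------------------------------------------------------------
# Follow-up simulation (for the response stage)

OUTCOME_PROBS = {"CR": 0.05, "PR_SD": 0.45, "PD_growth": 0.25, "PD_new": 0.25}


def simulate_followup(
    baseline_gt: np.ndarray,
    brain_mask: np.ndarray,
    spacing: Sequence[float],
    outcome: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Derive a co-registered follow-up mask realising a known outcome.

    CR empties the mask; PR_SD removes one lesion (partial response) or
    leaves the mask unchanged; PD_growth dilates lesions until total volume
    grows by >= 80%; PD_new adds a distant new lesion.
    """
    gt = np.asarray(baseline_gt).astype(bool)
    if outcome == "CR":
        return np.zeros_like(gt)
    if outcome == "PR_SD":
        labels, n = ndimage.label(gt, structure=np.ones((3, 3, 3), bool))
        if n >= 2:
            drop = int(rng.integers(1, n + 1))
            return gt & (labels != drop)
        return gt.copy()
    if outcome == "PD_growth":
        base_count = gt.sum()
        grown = gt.copy()
        for _ in range(6):
            grown = ndimage.binary_dilation(grown) & brain_mask.astype(bool)
            if grown.sum() >= 1.8 * base_count:
                break
        return grown
    if outcome == "PD_new":
        grown = gt.copy()
        free = (
            ndimage.binary_erosion(brain_mask.astype(bool), iterations=4)
            & ~ndimage.binary_dilation(gt, iterations=3)
        )
        idx = np.argwhere(free)
        if len(idx) == 0:
            raise RuntimeError("no room for a new lesion in this phantom")
        center = idx[rng.integers(len(idx))]
        ball = np.zeros_like(gt)
        ball[tuple(center)] = True
        grown |= ndimage.binary_dilation(ball, iterations=2) & brain_mask.astype(bool)
        return grown
    raise ValueError(f"unknown outcome {outcome!r}")


EXPECTED_CATEGORY = {"CR": "CR", "PR_SD": "PR_SD", "PD_growth": "PD", "PD_new": "PD"}


def response_stage(
    phantoms: dict[int, PhantomVolume], config: RunConfig
) -> dict:
    """Simulate follow-ups, classify volumetric response, and compare the
    algorithmic classification against the constructed ('radiologist')
    outcome."""
    rng = np.random.default_rng(_sub_seed(config.seed, "response"))
    outcomes = list(OUTCOME_PROBS)
    probs = np.array([OUTCOME_PROBS[o] for o in outcomes])
    truth, predicted, results = [], [], []
    for pid in sorted(phantoms):
        ph = phantoms[pid]
        if not ph.gt_mask.any():
            continue
        outcome = outcomes[int(rng.choice(len(outcomes), p=probs))]
        fup_mask = simulate_followup(
            ph.gt_mask, ph.brain_mask, ph.spacing, outcome, rng
        )
        pair = TimepointPair(
            baseline=label_components(ph.gt_mask.astype(np.uint8), ph.spacing),
            followup=label_components(fup_mask.astype(np.uint8), ph.spacing),
        )
        corr = correspond_lesions(pair, config.response)
        result = classify_response(pair, corr, config.response)
        truth.append(EXPECTED_CATEGORY[outcome])
        predicted.append(result.category)
        results.append({"patient": pid, "truth": EXPECTED_CATEGORY[outcome], **result.to_dict()})
    stats = agreement_stats(truth, predicted)
    return {
        "n_pairs": stats.n,
        "percent_agreement": stats.percent_agreement,
        "icc_2_1": stats.icc,
        "icc_ci95": list(stats.icc_ci95) if stats.icc_ci95 else None,
        "confusion": stats.confusion.tolist(),
        "cases": results,
    }


# ---------------------------------------------------------------------------
# Full pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Phantoms -> stratified K-fold -> train -> predict -> postprocess ->
    pooled lesion metrics (-> optional simulated response stage).

    Returns the cohort report (also written to ``out_dir`` when set).
    Deterministic: replaying the same config yields an identical report.
    """
    stage = "cohort"
    try:
        cohort = generate_cohort(config)
        stage = "split"
        strata = {pid: patient_strata_from_catalog(ph) for pid, ph in cohort.items()}
        folds = stratified_kfold(strata, k=config.k_folds, seed=_sub_seed(config.seed, "kfold"))
        fold_reports = []
        all_phantoms: list[PhantomVolume] = []
        all_preds: list[np.ndarray] = []
        all_raw: list[np.ndarray] = []
        test_folds = [0] if config.single_fold else list(range(config.k_folds))
        for fold in test_folds:
            stage = f"train(fold {fold})"
            test_ids = folds.patients_in_fold(fold)
            train_ids = folds.training_patients(fold)
            if config.predictor == "network":
                net, history, _ = run_training(
                    config, phantoms=cohort, training_patients=train_ids
                )
            elif config.predictor == "oracle":
                net, history = None, []
            else:
                raise ValueError(f"unknown predictor {config.predictor!r}")
            stage = f"predict(fold {fold})"
            phantoms = [cohort[i] for i in test_ids]
            preds, raw_preds = [], []
            for ph in phantoms:
                suppressed, raw = predict_phantom(
                    net,
                    ph,
                    config.binarization,
                    shell_thickness_mm=config.shell_thickness_mm,
                    oracle=config.predictor == "oracle",
                    return_raw=True,
                )
                preds.append(suppressed)
                raw_preds.append(raw)
            stage = f"evaluate(fold {fold})"
            report = evaluate_fold(phantoms, preds)
            report["fold"] = fold
            report["test_patients"] = test_ids
            report["fp_per_scan_unsuppressed"] = evaluate_fold(phantoms, raw_preds)[
                "fp_per_scan"
            ]
            if history:
                report["final_training_loss"] = history[-1].get(
                    "loss", history[-1].get("validation_loss")
                )
            fold_reports.append(report)
            all_phantoms.extend(phantoms)
            all_preds.extend(preds)
            all_raw.extend(raw_preds)
        stage = "pool"
        pooled = evaluate_fold(all_phantoms, all_preds)
        pooled["fp_per_scan_unsuppressed"] = evaluate_fold(all_phantoms, all_raw)[
            "fp_per_scan"
        ]
        out = {
            "config": config.to_dict(),
            "fold_strata": folds.fold_strata,
            "folds": fold_reports,
            "pooled": pooled,
        }
        if config.with_response_stage:
            stage = "response"
            out["response"] = response_stage(cohort, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
    return out
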