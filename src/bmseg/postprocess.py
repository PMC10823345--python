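"""False-positive suppression on the foreground channel.

Black-blood imaging leaves two canonical mimics of enhancing metastases:
incompletely suppressed vessels near the brain surface and the choroid
plexus. Both are handled with masks applied to the foreground probability
map before (or to components after) binarization, followed by removal of
sub-threshold connected components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

CONNECTIVITY_STRUCTURE = np.ones((3, 3, 3), dtype=bool)  # 26-neighbourhood


@dataclass
class SuppressionMasks:
    surface_shell: np.ndarray
    choroid_mask: np.ndarray
    vessel_mask: np.ndarray | None = None  # optional known vessel FP source
    shell_thickness_mm: float = 2.0
    overlap_fraction_threshold: float = 0.5  # theta, component_filter mode only

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_fraction_threshold <= 1.0:
            raise ValueError("overlap_fraction_threshold must lie in (0, 1]")
        if self.surface_shell.shape != self.choroid_mask.shape:
            raise ValueError("surface shell and choroid masks must share a grid")
        if self.vessel_mask is not None and self.vessel_mask.shape != self.choroid_mask.shape:
            raise ValueError("vessel mask must share the prediction grid")

    def blocked_region(self) -> np.ndarray:
        blocked = self.surface_shell.astype(bool) | self.choroid_mask.astype(bool)
        if self.vessel_mask is not None:
            blocked |= self.vessel_mask.astype(bool)
        return blocked


@dataclass
class BinarizationConfig:
    probability_threshold: float = 0.5
    min_component_voxels: int = 2
    mode: str = "zero_probability"  # or "component_filter"

    def __post_init__(self) -> None:
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability_threshold must lie strictly in (0, 1)")
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be non-negative")
        if self.mode not in ("zero_probability", "component_filter"):
            raise ValueError(f"unknown suppression mode {self.mode!r}")


def make_surface_shell(
    brain_mask: np.ndarray, thickness_mm: float, spacing: Sequence[float]
) -> np.ndarray:
    """Brain-boundary band: brain minus brain eroded by thickness_mm.

    The erosion radius is rounded per axis (round(thickness/spacing) voxels),
    so anisotropic grids get an approximately metric shell.
    """
    brain = np.asarray(brain_mask).astype(bool)
    if not brain.any():
        raise ValueError("brain mask is empty")
    if thickness_mm < 0:
        raise ValueError("shell thickness must be non-negative")
    radii = [int(round(thickness_mm / s)) for s in spacing]
    if all(r == 0 for r in radii):
        return np.zeros_like(brain)
    eroded = brain
    for axis, r in enumerate(radii):
        if r == 0:
            continue
        shape = [1, 1, 1]
        shape[axis] = 2 * r + 1
        eroded = ndimage.binary_erosion(
            eroded, structure=np.ones(shape, dtype=bool), border_value=0
        )
    if not eroded.any():
        raise ValueError(
            f"shell thickness {thickness_mm} mm erodes the whole brain "
            f"(erosion radii {radii} voxels)"
        )
    return brain & ~eroded


def _drop_small(binary: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 1:
        return binary
    labels, n = ndimage.label(binary, structure=CONNECTIVITY_STRUCTURE)
    if n == 0:
        return binary
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[labels]


def suppress(
    prob_map: np.ndarray, masks: SuppressionMasks, cfg: BinarizationConfig
) -> np.ndarray:
    """Binarize a foreground probability map with mask-based FP suppression.

    ``zero_probability`` mode zeroes the probability inside the surface shell
    and choroid mask before thresholding — applied directly on the foreground
    channel. ``component_filter`` mode thresholds first, then removes any
    component whose fraction of voxels inside the masks reaches
    ``overlap_fraction_threshold`` (useful when zeroing would bisect a true
    lesion that touches the shell). Both modes finish by removing components
    smaller than ``min_component_voxels``; the output is always a subset of
    the plainly thresholded input.
    """
    prob = np.asarray(prob_map, dtype=np.float32)
    if prob.shape != masks.surface_shell.shape:
        raise ValueError(
            f"probability grid {prob.shape} does not match masks "
            f"{masks.surface_shell.shape}"
        )
    blocked = masks.blocked_region()
    if cfg.mode == "zero_probability":
        p = prob.copy()
        p[blocked] = 0.0
        binary = p > cfg.probability_threshold
    else:
        binary = prob > cfg.probability_threshold
        labels, n = ndimage.label(binary, structure=CONNECTIVITY_STRUCTURE)
        if n:
            total = np.bincount(labels.ravel(), minlength=n + 1)
            inside = np.bincount(
                labels[blocked].ravel(), minlength=n + 1
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = inside / np.maximum(total, 1)
            remove = frac >= masks.overlap_fraction_threshold
            remove[0] = False
            binary = binary & ~remove[labels]
    return _drop_small(binary, cfg.min_component_voxels)
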