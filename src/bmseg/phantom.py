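"""Synthetic black-blood T1 phantom generation.

Produces toy 3D volumes that mimic the appearance of contrast-enhanced
black-blood T1-weighted MRI of brain metastases: a dark background, a
mid-intensity ellipsoidal "brain", bright quasi-spherical metastases whose
non-enhancing necrotic cores are *excluded* from the ground truth (the
segmentation convention for volumetric response assessment), bright tubular
vessel distractors, and a bright choroid-plexus-like periventricular blob.
Every structure's mask is returned alongside the intensity grid, so detection
and suppression stages can be evaluated against exact ground truth without
any clinical data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

SIZE_THRESHOLD_MM = 10.0  # lesions with equivalent diameter <= 10 mm are "small"

CATALOG_COLUMNS = [
    "lesion_id",
    "cx_mm",
    "cy_mm",
    "cz_mm",
    "solid_volume_mm3",
    "equivalent_diameter_mm",
    "has_necrosis",
    "size_class",
]


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed without touching existing structures."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic volume.

    Intensities are arbitrary units on roughly [0, 1]; spatial parameters are
    in millimetres. ``necrosis_core_fraction`` is the ratio of core radius to
    lesion radius.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int = 5
    lesion_diameter_range: tuple[float, float] = (4.0, 14.0)
    necrosis_probability: float = 0.3
    necrosis_core_fraction: float = 0.5
    n_vessels: int = 3
    vessel_radius_mm: float = 1.0
    choroid_center_voxel: tuple[int, int, int] | None = None  # default: grid centre
    choroid_semiaxes_mm: tuple[float, float, float] = (6.0, 4.0, 4.0)
    intensity_background: float = 0.0
    intensity_brain: float = 0.2
    intensity_lesion_rim: float = 1.0
    intensity_necrotic_core: float = 0.35
    intensity_vessel: float = 0.9
    intensity_choroid: float = 0.85
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 positive reals, got {self.voxel_spacing}")
        lo, hi = self.lesion_diameter_range
        if lo <= 0 or lo > hi:
            raise ValueError(f"lesion_diameter_range must satisfy 0 < min <= max, got {(lo, hi)}")
        if self.n_lesions < 0 or self.n_vessels < 0:
            raise ValueError("n_lesions and n_vessels must be non-negative")
        if not 0.0 <= self.necrosis_probability <= 1.0:
            raise ValueError("necrosis_probability must lie in [0, 1]")
        if not 0.0 < self.necrosis_core_fraction < 1.0:
            raise ValueError("necrosis_core_fraction must lie in (0, 1)")
        if self.vessel_radius_mm <= 0:
            raise ValueError("vessel_radius_mm must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.intensity_necrotic_core >= self.intensity_lesion_rim:
            raise ValueError("necrotic core must be darker than the enhancing rim")
        extent_mm = [n * s for n, s in zip(self.grid_shape, self.voxel_spacing)]
        if any(2 * a > e for a, e in zip(self.choroid_semiaxes_mm, extent_mm)):
            raise ValueError("choroid semi-axes do not fit inside the grid")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in (
            "grid_shape",
            "voxel_spacing",
            "lesion_diameter_range",
            "choroid_semiaxes_mm",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("choroid_center_voxel") is not None:
            d["choroid_center_voxel"] = tuple(d["choroid_center_voxel"])
        return cls(**d)


@dataclass(frozen=True)
class LesionRecord:
    lesion_id: int
    centroid_mm: tuple[float, float, float]
    solid_volume_mm3: float
    equivalent_diameter_mm: float
    has_necrosis: bool
    size_class: str  # "small" (<= 10 mm) or "large"


@dataclass
class PhantomVolume:
    """A generated phantom: intensity grid, all structure masks, lesion catalog."""

    intensity: np.ndarray
    brain_mask: np.ndarray
    gt_mask: np.ndarray
    necrosis_mask: np.ndarray
    vessel_mask: np.ndarray
    choroid_mask: np.ndarray
    catalog: list[LesionRecord]
    spacing: tuple[float, float, float]
    spec: PhantomSpec | None = None


def equivalent_diameter_mm(volume_mm3: float) -> float:
    """Diameter of the sphere with the given volume: (6V/pi)^(1/3)."""
    if volume_mm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_mm3}")
    return float((6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0))


def size_class_of(diameter_mm: float) -> str:
    """Size stratum: 'small' iff diameter <= 10 mm (boundary inclusive)."""
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm}")
    return "small" if diameter_mm <= SIZE_THRESHOLD_MM else "large"


def lesion_volume(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Volume in mm^3 of a binary mask: voxel count times voxel volume."""
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing}")
    return float(np.count_nonzero(mask)) * spacing[0] * spacing[1] * spacing[2]


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center_vox: Sequence[float],
    semiaxes_vox: Sequence[float],
) -> np.ndarray:
    """Boolean mask of the axis-aligned ellipsoid (voxel-centre inclusion test)."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_vox, semiaxes_vox))
    return r2 <= 1.0


def _ball_structure(radius_vox: Sequence[float]) -> np.ndarray:
    """Ellipsoidal structuring element with the given per-axis voxel radii."""
    r = [max(int(np.ceil(x)), 0) for x in radius_vox]
    shape = tuple(2 * x + 1 for x in r)
    return _ellipsoid_mask(shape, r, [max(x, 1e-9) for x in radius_vox])


def generate_phantom(spec: PhantomSpec, max_retries: int = 2000) -> PhantomVolume:
    """Generate one phantom deterministically from ``spec.seed``.

    Lesions are mildly anisotropic ellipsoids (axis scale factors drawn from
    [0.8, 1.25]) placed by rejection sampling with a 2-voxel clearance from
    each other and from the choroid region. A lesion flagged necrotic carries
    a darker inner core whose voxels are excluded from ``gt_mask``. Vessels
    are random-walk centerlines dilated to ``vessel_radius_mm``; vessel voxels
    never overwrite lesion voxels. Gaussian noise is added last.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)

    # Brain: ellipsoid filling most of the grid.
    center = [(n - 1) / 2.0 for n in shape]
    brain_semiaxes = [0.45 * n for n in shape]
    brain_mask = _ellipsoid_mask(shape, center, brain_semiaxes)

    # Choroid-plexus-like blob near the centre of the brain.
    cp_center = spec.choroid_center_voxel or tuple(int(c) for c in center)
    cp_semiaxes_vox = [a / s for a, s in zip(spec.choroid_semiaxes_mm, spacing)]
    choroid_mask = _ellipsoid_mask(shape, cp_center, cp_semiaxes_vox) & brain_mask

    gt_mask = np.zeros(shape, dtype=bool)
    necrosis_mask = np.zeros(shape, dtype=bool)
    # Occupied zone lesions must stay clear of: choroid + already-placed
    # lesions (each with a 2-voxel gap) + a 3-voxel band at the brain surface
    # (so a metric surface shell never clips a true lesion).
    gap_structure = np.ones((5, 5, 5), dtype=bool)
    blocked = ndimage.binary_dilation(choroid_mask, structure=gap_structure)
    interior = brain_mask
    for axis in range(3):  # box erosion, radius 3 (Chebyshev metric)
        st_shape = [1, 1, 1]
        st_shape[axis] = 7
        interior = ndimage.binary_erosion(
            interior, structure=np.ones(st_shape, dtype=bool), border_value=0
        )
    blocked |= ~interior

    records: list[LesionRecord] = []
    lo_d, hi_d = spec.lesion_diameter_range
    for lesion_id in range(1, spec.n_lesions + 1):
        diameter = rng.uniform(lo_d, hi_d)
        if diameter <= 0:
            raise ValueError(f"lesion {lesion_id}: requested non-positive diameter")
        aniso = rng.uniform(0.8, 1.25, size=3)
        semiaxes_mm = 0.5 * diameter * aniso
        semiaxes_vox = semiaxes_mm / spacing
        has_necrosis = bool(rng.random() < spec.necrosis_probability)

        placed = False
        for _ in range(max_retries):
            # Keep the whole lesion inside the brain: sample the centre from
            # the brain eroded by the lesion's bounding radius (+1 margin).
            margin = semiaxes_vox + 1.0
            cand = np.array(
                [rng.uniform(m, n - 1 - m) for m, n in zip(margin, shape)]
            )
            lesion = _ellipsoid_mask(shape, cand, semiaxes_vox)
            if not lesion.any():
                raise ValueError(f"lesion {lesion_id}: zero-volume lesion request")
            if (lesion & ~brain_mask).any() or (lesion & blocked).any():
                continue
            rim = lesion
            core = np.zeros(shape, dtype=bool)
            if has_necrosis:
                core = _ellipsoid_mask(
                    shape, cand, semiaxes_vox * spec.necrosis_core_fraction
                )
                rim = lesion & ~core
                if not rim.any():  # core swallowed the lesion at this resolution
                    continue
            gt_mask |= rim
            necrosis_mask |= core
            blocked |= ndimage.binary_dilation(lesion, structure=gap_structure)
            vol = lesion_volume(rim, spacing)
            idx = np.argwhere(rim)
            centroid = tuple((idx.mean(axis=0) * spacing).tolist())
            diam = equivalent_diameter_mm(vol)
            records.append(
                LesionRecord(
                    lesion_id=lesion_id,
                    centroid_mm=centroid,
                    solid_volume_mm3=vol,
                    equivalent_diameter_mm=diam,
                    has_necrosis=has_necrosis,
                    size_class=size_class_of(diam),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place lesion {lesion_id} (diameter {diameter:.1f} mm) "
                f"after {max_retries} attempts; grid too crowded"
            )

    # Vessels: random-walk centerlines dilated to tubes; never overwrite lesions.
    vessel_mask = np.zeros(shape, dtype=bool)
    if spec.n_vessels > 0:
        tube = _ball_structure(spec.vessel_radius_mm / spacing)
        n_steps = int(1.5 * max(shape))
        for _ in range(spec.n_vessels):
            center_line = np.zeros(shape, dtype=bool)
            pos = np.array(
                [rng.uniform(0.25 * n, 0.75 * n) for n in shape], dtype=float
            )
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            for _ in range(n_steps):
                ijk = tuple(np.clip(np.round(pos).astype(int), 0, np.array(shape) - 1))
                center_line[ijk] = True
                direction += 0.3 * rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = pos + direction
                if not all(0 <= p < n for p, n in zip(pos, shape)):
                    break
            vessel_mask |= ndimage.binary_dilation(center_line, structure=tube)
    vessel_mask &= brain_mask
    vessel_mask &= ~(gt_mask | necrosis_mask)

    intensity = np.full(shape, spec.intensity_background, dtype=np.float32)
    intensity[brain_mask] = spec.intensity_brain
    intensity[vessel_mask] = spec.intensity_vessel
    intensity[choroid_mask] = spec.intensity_choroid
    intensity[necrosis_mask] = spec.intensity_necrotic_core
    intensity[gt_mask] = spec.intensity_lesion_rim
    if spec.noise_sigma > 0:
        intensity = intensity + rng.normal(
            0.0, spec.noise_sigma, size=shape
        ).astype(np.float32)

    return PhantomVolume(
        intensity=intensity.astype(np.float32),
        brain_mask=brain_mask,
        gt_mask=gt_mask,
        necrosis_mask=necrosis_mask,
        vessel_mask=vessel_mask,
        choroid_mask=choroid_mask,
        catalog=records,
        spacing=tuple(spacing.tolist()),
        spec=spec,
    )


def catalog_to_frame(catalog: list[LesionRecord]) -> pd.DataFrame:
    rows = [
        {
            "lesion_id": r.lesion_id,
            "cx_mm": r.centroid_mm[0],
            "cy_mm": r.centroid_mm[1],
            "cz_mm": r.centroid_mm[2],
            "solid_volume_mm3": r.solid_volume_mm3,
            "equivalent_diameter_mm": r.equivalent_diameter_mm,
            "has_necrosis": r.has_necrosis,
            "size_class": r.size_class,
        }
        for r in catalog
    ]
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_nifti(grid: np.ndarray, spacing: Sequence[float], path: Path) -> None:
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    nib.save(nib.Nifti1Image(grid, _affine(spacing)), str(path))


def load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def write_phantom(volume: PhantomVolume, directory: str | Path) -> dict:
    """Write the phantom as NIfTI volumes + catalog CSV + manifest JSON.

    The manifest embeds the generating spec, so the directory round-trips:
    regenerating from the manifest's spec reproduces the files bit-for-bit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    grids = {
        "intensity": volume.intensity,
        "brain_mask": volume.brain_mask,
        "gt_mask": volume.gt_mask,
        "necrosis_mask": volume.necrosis_mask,
        "vessel_mask": volume.vessel_mask,
        "choroid_mask": volume.choroid_mask,
    }
    try:
        for name, grid in grids.items():
            fname = f"{name}.nii.gz"
            save_nifti(grid, volume.spacing, directory / fname)
            files[name] = fname
        catalog_to_frame(volume.catalog).to_csv(directory / "catalog.csv", index=False)
        files["catalog"] = "catalog.csv"
        manifest = {
            "files": files,
            "spacing": list(volume.spacing),
            "spec": volume.spec.to_dict() if volume.spec is not None else None,
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except OSError as exc:
        raise OSError(f"failed writing phantom to {directory}: {exc}") from exc
    return manifest


def read_phantom(directory: str | Path) -> PhantomVolume:
    """Load a phantom previously written by :func:`write_phantom`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    files = manifest["files"]
    spacing = tuple(manifest["spacing"])

    def grid(name, dtype=None):
        arr, _ = load_nifti(directory / files[name])
        return arr.astype(dtype) if dtype else arr

    frame = pd.read_csv(directory / files["catalog"])
    catalog = [
        LesionRecord(
            lesion_id=int(row.lesion_id),
            centroid_mm=(row.cx_mm, row.cy_mm, row.cz_mm),
            solid_volume_mm3=float(row.solid_volume_mm3),
            equivalent_diameter_mm=float(row.equivalent_diameter_mm),
            has_necrosis=bool(row.has_necrosis),
            size_class=str(row.size_class),
        )
        for row in frame.itertuples()
    ]
    spec = PhantomSpec.from_dict(manifest["spec"]) if manifest.get("spec") else None
    return PhantomVolume(
        intensity=grid("intensity", np.float32),
        brain_mask=grid("brain_mask").astype(bool),
        gt_mask=grid("gt_mask").astype(bool),
        necrosis_mask=grid("necrosis_mask").astype(bool),
        vessel_mask=grid("vessel_mask").astype(bool),
        choroid_mask=grid("choroid_mask").astype(bool),
        catalog=catalog,
        spacing=spacing,
        spec=spec,
    )
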