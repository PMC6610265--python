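"""Threshold-based ROI/VOI segmentation of the late summed PET image.

Implements the five region definitions used in clinical dynamic [18F]FET
evaluation, all operating on the summed (late-window) SUV image:

* ``ROI90`` / ``VOI90`` — region growing at 90% of the lesion maximum, in the
  max-uptake axial slice (2D) or in three dimensions;
* ``ROI_TBR`` / ``VOI_TBR`` — region growing at 1.6x the contralateral
  background concentration (2-cm background sphere);
* ``VOI_FIX`` — a ~2 mL sphere (1.56 cm diameter) centred on the maximum;

plus fixed 1-cm spheres (``SPHERE_MANUAL``) for location-matched comparisons,
and a plausibility check that rejects segmentations flooding beyond the brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageGeometry, RegionMask, RegionError, StaticImage

ROI90 = "ROI90"
VOI90 = "VOI90"
ROI_TBR = "ROI_TBR"
VOI_TBR = "VOI_TBR"
VOI_FIX = "VOI_FIX"
SPHERE_MANUAL = "SPHERE_MANUAL"

THRESHOLD_DEFINITIONS = (ROI90, VOI90, ROI_TBR, VOI_TBR)
ALL_DEFINITIONS = (ROI90, VOI90, ROI_TBR, VOI_TBR, VOI_FIX)


class SeedBelowThresholdError(RegionError):
    """Region growing cannot start: the seed value lies below the threshold."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the ROI/VOI definitions.

    Defaults follow the published methodology: 90%-of-maximum and
    1.6x-background thresholds (both inclusive), a 20 mm background sphere,
    a 15.6 mm (~2 mL) fixed VOI, 10 mm manual spheres.  The exclusion limits
    operationalise "segmentation flooded the head": a mask larger than
    ``max_plausible_volume_ml`` or with more than ``max_outside_brain_fraction``
    of its voxels outside a supplied brain mask is excluded.
    """

    rel_threshold_max: float = 0.90
    tbr_threshold: float = 1.6
    background_diameter_mm: float = 20.0
    fix_diameter_mm: float = 15.6
    manual_sphere_diameter_mm: float = 10.0
    connectivity_3d: int = 26
    connectivity_2d: int = 8
    max_plausible_volume_ml: float = 50.0
    max_outside_brain_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.rel_threshold_max <= 1:
            raise ValueError("rel_threshold_max must lie in (0, 1]")
        if self.tbr_threshold <= 0:
            raise ValueError("tbr_threshold must be positive")
        for name in (
            "background_diameter_mm",
            "fix_diameter_mm",
            "manual_sphere_diameter_mm",
            "max_plausible_volume_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.connectivity_3d not in (6, 18, 26):
            raise ValueError("connectivity_3d must be 6, 18 or 26")
        if self.connectivity_2d not in (4, 8):
            raise ValueError("connectivity_2d must be 4 or 8")


@dataclass(frozen=True)
class PlausibilityResult:
    passed: bool
    reason: str | None = None


_STRUCT_3D = {6: 1, 18: 2, 26: 3}
_STRUCT_2D = {4: 1, 8: 2}


def _structure_3d(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, _STRUCT_3D[connectivity])


def _structure_2d(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, _STRUCT_2D[connectivity])


def find_max_voxel(
    img: StaticImage, search: RegionMask | np.ndarray | None = None
) -> tuple[int, int, int]:
    """Index of the maximum value, optionally restricted to a search region.

    Ties are broken toward the lexicographically smallest (z, y, x) index.
    """
    vals = img.values
    if search is None:
        flat = int(np.argmax(vals))  # first occurrence = lexicographic smallest
        return tuple(int(i) for i in np.unravel_index(flat, vals.shape))
    if isinstance(search, RegionMask):
        region = search.to_array(vals.shape)
    else:
        region = np.asarray(search, dtype=bool)
        if region.shape != vals.shape:
            raise RegionError("search mask shape does not match image")
    if not region.any():
        raise RegionError("search region is empty")
    masked = np.where(region, vals, -np.inf)
    flat = int(np.argmax(masked))
    return tuple(int(i) for i in np.unravel_index(flat, vals.shape))


def region_grow(
    img: StaticImage,
    seed: tuple[int, int, int],
    threshold: float,
    mode: str = "3d",
    config: SegmentationConfig | None = None,
    definition: str = "MANUAL",
) -> RegionMask:
    """Connected component of {voxels >= threshold} containing the seed.

    ``mode='2d'`` restricts growth to the seed's axial slice (8-neighbourhood
    by default); ``mode='3d'`` grows through the volume (26-neighbourhood).
    The threshold is inclusive.
    """
    config = config or SegmentationConfig()
    seed = tuple(int(i) for i in seed)
    if not img.geometry.contains_index(seed):
        raise RegionError(f"seed {seed} outside the image")
    if img.values[seed] < threshold:
        raise SeedBelowThresholdError(
            f"seed value {img.values[seed]:.4g} is below threshold {threshold:.4g}"
        )
    above = img.values >= threshold
    if mode == "3d":
        labels, _ = ndimage.label(above, structure=_structure_3d(config.connectivity_3d))
        comp = labels == labels[seed]
        voxels = np.argwhere(comp)
        return RegionMask(voxels, dimensionality=3, definition=definition)
    if mode == "2d":
        z = seed[0]
        labels, _ = ndimage.label(
            above[z], structure=_structure_2d(config.connectivity_2d)
        )
        comp = labels == labels[seed[1], seed[2]]
        yx = np.argwhere(comp)
        voxels = np.column_stack([np.full(len(yx), z), yx])
        return RegionMask(
            voxels, dimensionality=2, definition=definition, slice_index=z
        )
    raise ValueError("mode must be '2d' or '3d'")


def _resolve_seed(
    summed: StaticImage, tumour_hint: RegionMask | np.ndarray | tuple | None
) -> tuple[int, int, int]:
    """Max-uptake voxel within the tumour hint (or the whole volume)."""
    if isinstance(tumour_hint, tuple) and len(tumour_hint) == 3 and all(
        np.isscalar(i) for i in tumour_hint
    ):
        seed = tuple(int(i) for i in tumour_hint)
        if not summed.geometry.contains_index(seed):
            raise RegionError(f"seed {seed} outside the image")
        return seed
    return find_max_voxel(summed, tumour_hint)


def segment_roi90(
    summed: StaticImage,
    tumour_hint: RegionMask | np.ndarray | tuple | None = None,
    config: SegmentationConfig | None = None,
) -> RegionMask:
    """2D region at >= 90% of the tumour maximum, in the max-uptake slice."""
    config = config or SegmentationConfig()
    seed = _resolve_seed(summed, tumour_hint)
    thr = config.rel_threshold_max * summed.values[seed]
    return region_grow(summed, seed, thr, mode="2d", config=config, definition=ROI90)


def segment_voi90(
    summed: StaticImage,
    tumour_hint: RegionMask | np.ndarray | tuple | None = None,
    config: SegmentationConfig | None = None,
) -> RegionMask:
    """3D region at >= 90% of the tumour maximum."""
    config = config or SegmentationConfig()
    seed = _resolve_seed(summed, tumour_hint)
    thr = config.rel_threshold_max * summed.values[seed]
    return region_grow(summed, seed, thr, mode="3d", config=config, definition=VOI90)


def sphere_voi(
    geometry: ImageGeometry,
    center_world: tuple[float, float, float],
    diameter_mm: float,
    definition: str = VOI_FIX,
) -> RegionMask:
    """All voxels whose centres lie within diameter/2 of a world-space point."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    zz, yy, xx = geometry.meshgrid()
    r2 = (
        (zz - center_world[0]) ** 2
        + (yy - center_world[1]) ** 2
        + (xx - center_world[2]) ** 2
    )
    inside = r2 <= (diameter_mm / 2.0) ** 2
    if not inside.any():
        raise RegionError("sphere does not contain any voxel centre")
    return RegionMask(np.argwhere(inside), dimensionality=3, definition=definition)


def background_mean(
    summed: StaticImage,
    center: tuple[int, int, int],
    diameter_mm: float | None = None,
    config: SegmentationConfig | None = None,
) -> float:
    """Mean SUV in a spherical background VOI centred on a voxel index.

    The sphere (default 2 cm diameter) must lie fully inside the volume.
    """
    config = config or SegmentationConfig()
    d = diameter_mm if diameter_mm is not None else config.background_diameter_mm
    geom = summed.geometry
    center_world = geom.voxel_to_world(tuple(int(i) for i in center))
    r = d / 2.0
    for a in range(3):
        lo = geom.origin[a] - geom.spacing[a] / 2.0
        hi = lo + geom.spacing[a] * geom.shape[a]
        if center_world[a] - r < lo or center_world[a] + r > hi:
            raise RegionError("background sphere exceeds the volume bounds")
    sphere = sphere_voi(geom, center_world, d, definition="BACKGROUND")
    return float(summed.values[sphere.indexer()].mean())


def segment_tbr(
    summed: StaticImage,
    tumour_hint: RegionMask | np.ndarray | tuple | None,
    background: float,
    mode: str = "2d",
    config: SegmentationConfig | None = None,
) -> RegionMask:
    """Region grown at >= 1.6x the background concentration (absolute)."""
    config = config or SegmentationConfig()
    if background <= 0:
        raise ValueError("background must be positive")
    seed = _resolve_seed(summed, tumour_hint)
    thr = config.tbr_threshold * background
    definition = ROI_TBR if mode == "2d" else VOI_TBR
    return region_grow(
        summed, seed, thr, mode=mode, config=config, definition=definition
    )


def mirror_across_midsagittal(
    geometry: ImageGeometry, index: tuple[int, int, int]
) -> tuple[int, int, int]:
    """Reflect a voxel index across the mid-sagittal (x mid) plane."""
    z, y, x = index
    return int(z), int(y), int(round(geometry.shape[2] - 1 - x))


def plausibility_check(
    mask: RegionMask,
    geometry: ImageGeometry,
    config: SegmentationConfig | None = None,
    brain_mask: RegionMask | np.ndarray | None = None,
) -> PlausibilityResult:
    """Reject segmentations too large to be a lesion or escaping the brain.

    Operationalises the exclusion of thresholds "too low for a meaningful
    segmentation": excluded when the mask volume exceeds
    ``max_plausible_volume_ml`` or, given a brain mask, when more than
    ``max_outside_brain_fraction`` of its voxels fall outside the brain.
    """
    config = config or SegmentationConfig()
    if mask.is_empty:
        return PlausibilityResult(False, "empty segmentation")
    vol = mask.volume_ml(geometry)
    if vol > config.max_plausible_volume_ml:
        return PlausibilityResult(
            False,
            f"segmented volume {vol:.1f} mL exceeds "
            f"{config.max_plausible_volume_ml:.0f} mL",
        )
    if brain_mask is not None:
        if isinstance(brain_mask, RegionMask):
            brain = brain_mask.to_array(geometry.shape)
        else:
            brain = np.asarray(brain_mask, dtype=bool)
        inside = brain[mask.indexer()]
        frac_out = 1.0 - inside.mean()
        if frac_out > config.max_outside_brain_fraction:
            return PlausibilityResult(
                False, f"{100 * frac_out:.0f}% of segmented voxels outside the brain"
            )
    return PlausibilityResult(True)
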