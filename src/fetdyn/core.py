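"""Data model for dynamic brain-PET volumes.

Frame schedules, voxel geometry, 4D dynamic and 3D static images (SUV units),
region masks, NIfTI I/O and time-windowed image derivation.  All arrays are
indexed ``(frame, z, y, x)``; world coordinates are millimetres with the NIfTI
affine restricted to axis-aligned scaling plus translation.  Time is minutes
from tracer injection, which coincides with the acquisition start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("fetdyn")

#: Frame edges (minutes) of the standard 40-min acquisition:
#: 2 x 2 min, 4 x 4 min, 2 x 10 min.
STANDARD_FRAME_EDGES = (0.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 30.0, 40.0)

SCHEDULE_FORMAT = "fetdyn-schedule/1"


class FetdynError(Exception):
    """Base class for errors raised by this package."""


class ScheduleError(FetdynError):
    """Invalid frame schedule, or schedule/image mismatch."""


class WindowError(FetdynError):
    """Requested time window cannot be represented by whole frames."""


class RegionError(FetdynError):
    """Invalid region: empty search region, out-of-bounds voxels, ..."""


@dataclass(frozen=True)
class FrameSchedule:
    """A contiguous partition of the acquisition into reconstruction frames.

    Frames are ``(start_min, end_min)`` pairs, gap-free, starting at 0.
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        frames = tuple((float(a), float(b)) for a, b in self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise ScheduleError("schedule has no frames")
        if frames[0][0] != 0.0:
            raise ScheduleError("first frame must start at 0 min")
        for i, (a, b) in enumerate(frames):
            if not b > a:
                raise ScheduleError(f"frame {i} has non-positive duration")
            if i and frames[i - 1][1] != a:
                raise ScheduleError(f"frames {i - 1} and {i} are not contiguous")

    @classmethod
    def standard(cls) -> "FrameSchedule":
        """The eight-frame schedule ending at [2, 4, 8, 12, 16, 20, 30, 40] min."""
        e = STANDARD_FRAME_EDGES
        return cls(tuple(zip(e[:-1], e[1:])))

    @classmethod
    def from_edges(cls, edges: Sequence[float]) -> "FrameSchedule":
        return cls(tuple(zip(edges[:-1], edges[1:])))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([a for a, _ in self.frames])

    @property
    def ends(self) -> np.ndarray:
        return np.array([b for _, b in self.frames])

    @property
    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.frames])

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([[self.frames[0][0]], self.ends])

    def snap(self, t: float) -> float:
        """Nearest frame edge to time ``t`` (minutes)."""
        edges = self.edges
        return float(edges[int(np.argmin(np.abs(edges - t)))])

    def window_frames(
        self, start_min: float, end_min: float, snap: bool = True
    ) -> tuple[list[int], tuple[float, float]]:
        """Frame indices covering ``[start_min, end_min]``.

        The window must be a union of whole frames.  With ``snap=True`` (the
        default) each endpoint is moved to the nearest frame edge first and a
        warning is logged when it moves; otherwise a misaligned window raises
        :class:`WindowError`.
        """
        edges = self.edges
        s, e = float(start_min), float(end_min)
        if snap:
            s2, e2 = self.snap(s), self.snap(e)
            if (s2, e2) != (s, e):
                logger.warning(
                    "window (%g, %g) min snapped to frame edges (%g, %g)", s, e, s2, e2
                )
            s, e = s2, e2
        if s not in edges or e not in edges:
            raise WindowError(f"window ({start_min}, {end_min}) is not frame-aligned")
        if not e > s:
            raise WindowError("window is empty after snapping")
        idx = [i for i, (a, b) in enumerate(self.frames) if a >= s and b <= e]
        return idx, (s, e)

    def to_dict(self) -> dict:
        return {"format": SCHEDULE_FORMAT, "frames": [list(f) for f in self.frames]}

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        try:
            frames = d["frames"]
        except (KeyError, TypeError) as exc:
            raise ScheduleError("schedule file lacks a 'frames' list") from exc
        return cls(tuple((float(a), float(b)) for a, b in frames))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "FrameSchedule":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ImageGeometry:
    """Axis-aligned voxel grid: shape/spacing/origin in ``(z, y, x)`` order.

    ``origin`` is the world coordinate (mm) of the centre of voxel (0, 0, 0);
    z is the axial direction.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError("shape must be three positive integers")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def voxel_volume_ml(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one (z, y, x) axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate grids (zz, yy, xx), in mm."""
        z = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        x = self.axis_coords(2)[None, None, :]
        return z, y, x

    @property
    def center_world(self) -> tuple[float, float, float]:
        return tuple(
            self.origin[a] + self.spacing[a] * (self.shape[a] - 1) / 2.0
            for a in range(3)
        )

    def voxel_to_world(self, index: Sequence[float]) -> tuple[float, float, float]:
        return tuple(self.origin[a] + self.spacing[a] * index[a] for a in range(3))

    def world_to_voxel(self, point: Sequence[float]) -> tuple[float, float, float]:
        return tuple((point[a] - self.origin[a]) / self.spacing[a] for a in range(3))

    def contains_index(self, index: Sequence[int]) -> bool:
        return all(0 <= index[a] < self.shape[a] for a in range(3))

    def affine(self) -> np.ndarray:
        """NIfTI affine for data stored in (x, y, z[, t]) axis order."""
        dz, dy, dx = self.spacing
        z0, y0, x0 = self.origin
        aff = np.diag([dx, dy, dz, 1.0])
        aff[:3, 3] = [x0, y0, z0]
        return aff

    @classmethod
    def from_affine(cls, shape_xyz: Sequence[int], affine: np.ndarray) -> "ImageGeometry":
        scales = np.abs(np.diag(affine)[:3])
        if np.any(scales <= 0):
            raise ValueError("affine has non-positive scales")
        off = affine[:3, 3]
        nx, ny, nz = shape_xyz
        return cls(
            shape=(int(nz), int(ny), int(nx)),
            spacing=(float(scales[2]), float(scales[1]), float(scales[0])),
            origin=(float(off[2]), float(off[1]), float(off[0])),
        )


@dataclass
class DynamicImage:
    """A 4D dynamic PET image in SUV units with its frame schedule."""

    geometry: ImageGeometry
    schedule: FrameSchedule
    values: np.ndarray  # (n_frames, nz, ny, nx)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError("dynamic image values must be 4D (frame, z, y, x)")
        if self.values.shape[0] != self.schedule.n_frames:
            raise ScheduleError(
                f"image has {self.values.shape[0]} frames but schedule has "
                f"{self.schedule.n_frames}"
            )
        if self.values.shape[1:] != self.geometry.shape:
            raise ValueError("image shape does not match geometry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dynamic image contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.schedule.n_frames

    def frame(self, i: int) -> np.ndarray:
        return self.values[i]

    def scaled(self, a: float) -> "DynamicImage":
        return DynamicImage(self.geometry, self.schedule, self.values * a)


@dataclass
class StaticImage:
    """A 3D SUV image derived from a time window of a dynamic acquisition."""

    geometry: ImageGeometry
    values: np.ndarray
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("static image values must be 3D (z, y, x)")
        if self.values.shape != self.geometry.shape:
            raise ValueError("image shape does not match geometry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("static image contains non-finite values")


@dataclass
class RegionMask:
    """A set of voxel indices on a reference grid (a ROI or VOI).

    ``dimensionality`` 2 means a single-axial-slice region (a ROI in the
    clinical sense); 3 means a volume.  ``definition`` records which ROI/VOI
    rule produced the mask.
    """

    voxels: np.ndarray  # (n, 3) integer (z, y, x) indices
    dimensionality: int = 3
    definition: str = "MANUAL"
    slice_index: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.intp)
        if v.size == 0:
            v = v.reshape(0, 3)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("voxels must be an (n, 3) index array")
        v = np.unique(v, axis=0)
        self.voxels = v
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if self.dimensionality == 2 and len(v):
            zs = np.unique(v[:, 0])
            if len(zs) != 1:
                raise ValueError("a 2D mask must live in a single axial slice")
            self.slice_index = int(zs[0])

    @classmethod
    def from_array(
        cls, arr: np.ndarray, dimensionality: int = 3, definition: str = "MANUAL"
    ) -> "RegionMask":
        return cls(
            np.argwhere(np.asarray(arr) != 0),
            dimensionality=dimensionality,
            definition=definition,
        )

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def is_empty(self) -> bool:
        return len(self.voxels) == 0

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.voxels.tolist()}

    def volume_ml(self, geometry: ImageGeometry) -> float:
        return self.n_voxels * geometry.voxel_volume_ml

    def to_array(self, shape: tuple[int, int, int]) -> np.ndarray:
        arr = np.zeros(shape, dtype=bool)
        if len(self.voxels):
            if (self.voxels < 0).any() or (self.voxels >= np.array(shape)).any():
                raise RegionError("mask voxel index outside geometry")
            arr[tuple(self.voxels.T)] = True
        return arr

    def indexer(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fancy-index tuple selecting the mask voxels from a (z, y, x) array."""
        if self.is_empty:
            raise RegionError("mask is empty")
        return tuple(self.voxels.T)

    def centroid(self) -> tuple[float, float, float]:
        if self.is_empty:
            raise RegionError("mask is empty")
        return tuple(self.voxels.mean(axis=0))

    def intersect_slice(self, z: int) -> "RegionMask":
        sel = self.voxels[self.voxels[:, 0] == z]
        return RegionMask(sel, dimensionality=2, definition=self.definition)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _to_xyzt(values: np.ndarray) -> np.ndarray:
    # (frame, z, y, x) -> (x, y, z, frame)
    return np.transpose(values, (3, 2, 1, 0))


def _from_xyzt(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (3, 2, 1, 0))


def save_dynamic(img: DynamicImage, image_path: str | Path, schedule_path: str | Path) -> None:
    """Write a 4D NIfTI plus its frame-schedule sidecar."""
    nii = nib.Nifti1Image(
        _to_xyzt(img.values).astype(np.float32), img.geometry.affine()
    )
    nib.save(nii, str(image_path))
    img.schedule.save(schedule_path)


def load_dynamic(image_path: str | Path, schedule_path: str | Path) -> DynamicImage:
    """Load a 4D NIfTI and its frame-schedule sidecar into a DynamicImage."""
    image_path, schedule_path = Path(image_path), Path(schedule_path)
    if not image_path.exists():
        raise FileNotFoundError(image_path)
    if not schedule_path.exists():
        raise FileNotFoundError(schedule_path)
    nii = nib.load(str(image_path))
    data = np.asanyarray(nii.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{image_path} is not a 4D image")
    schedule = FrameSchedule.load(schedule_path)
    if data.shape[3] != schedule.n_frames:
        raise ScheduleError(
            f"image has {data.shape[3]} frames but schedule lists {schedule.n_frames}"
        )
    values = _from_xyzt(data).astype(np.float64)
    for f in range(values.shape[0]):
        if np.all(np.isnan(values[f])):
            raise ValueError(f"frame {f} of {image_path} is all-NaN")
    geometry = ImageGeometry.from_affine(data.shape[:3], nii.affine)
    return DynamicImage(geometry, schedule, values)


def save_static(img: StaticImage, path: str | Path) -> None:
    nii = nib.Nifti1Image(
        np.transpose(img.values, (2, 1, 0)).astype(np.float32), img.geometry.affine()
    )
    nib.save(nii, str(path))


def save_mask(mask: RegionMask, geometry: ImageGeometry, path: str | Path) -> None:
    """Write a mask as a 3D NIfTI of 0/1 labels on the given geometry."""
    arr = mask.to_array(geometry.shape).astype(np.uint8)
    nii = nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), geometry.affine())
    nib.save(nii, str(path))


def load_mask(path: str | Path, definition: str = "MANUAL") -> tuple[RegionMask, ImageGeometry]:
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj)
    geometry = ImageGeometry.from_affine(data.shape, nii.affine)
    arr = np.transpose(data, (2, 1, 0))
    return RegionMask.from_array(arr, definition=definition), geometry


# ---------------------------------------------------------------------------
# Windowed derivation
# ---------------------------------------------------------------------------

def windowed_mean_image(
    img: DynamicImage, start_min: float, end_min: float, snap: bool = True
) -> StaticImage:
    """Duration-weighted mean SUV image over a frame-aligned time window.

    The clinical "summed" late image: SUV is intensive, so frames are averaged
    with their durations as weights rather than summed.  Windows that do not
    land on frame edges are snapped to the nearest edge (logged) unless
    ``snap=False``, in which case they raise :class:`WindowError`.
    """
    idx, (s, e) = img.schedule.window_frames(start_min, end_min, snap=snap)
    w = img.schedule.durations[idx]
    vals = np.tensordot(w, img.values[idx], axes=(0, 0)) / w.sum()
    return StaticImage(img.geometry, vals, window=(s, e))
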