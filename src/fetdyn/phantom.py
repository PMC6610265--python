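"""Synthetic 4D dynamic brain-PET phantoms with attenuation-correction bias.

The generator emulates a 40-min dynamic amino-acid PET acquisition: a brain
background, spherical lesions following one of three canonical kinetic
families (saturating increase, gamma-variate early/late peak, constant),
physiological confounders (an early-peaking vessel, a scalp shell),
frame-duration-dependent Gaussian noise, and time-independent spatially
smooth multiplicative bias fields standing in for different attenuation
correction (AC) methods.  Because every frame of a dynamic study is corrected
with the same AC map, an AC error acts as a single 3D multiplicative field
applied to all frames — that is exactly what :func:`apply_bias` does.

Image reconstruction itself (projection, scatter, real attenuation maps) is
out of scope; the phantom works directly in SUV image space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, ndimage

from .core import DynamicImage, FrameSchedule, ImageGeometry, RegionMask
from .kinetics import ClassifierConfig, TimeActivityCurve, classify_pattern_3

#: Reference frame duration (min) for the noise model.
NOISE_REF_DURATION_MIN = 10.0


# ---------------------------------------------------------------------------
# Kinetic models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticModel:
    """Analytic tracer concentration C(t), in SUV, for one tissue class.

    families
        ``increasing``     C(t) = A (1 - exp(-t/tau)) — saturating uptake.
        ``gamma_variate``  C(t) = A (t/tp)^alpha exp(alpha (1 - t/tp)) —
                           unique maximum A at t = tp (alpha > 0).
        ``constant``       C(t) = A.
    """

    family: str
    amplitude: float
    tau: float | None = None
    tp: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("increasing", "gamma_variate", "constant"):
            raise ValueError(f"unknown kinetic family {self.family!r}")
        if self.family == "increasing" and (self.tau is None or self.tau <= 0):
            raise ValueError("increasing family needs tau > 0")
        if self.family == "gamma_variate" and (
            self.tp is None or self.tp <= 0 or self.alpha is None or self.alpha <= 0
        ):
            raise ValueError("gamma_variate family needs tp > 0 and alpha > 0")

    def value(self, t: float | np.ndarray) -> np.ndarray | float:
        """Evaluate C(t) for t >= 0 (minutes)."""
        t = np.asarray(t, dtype=np.float64)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        A = self.amplitude
        if self.family == "constant":
            out = np.full_like(t, A)
        elif self.family == "increasing":
            out = A * (1.0 - np.exp(-t / self.tau))
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = t / self.tp
                out = A * ratio**self.alpha * np.exp(self.alpha * (1.0 - ratio))
            out = np.where(t == 0, 0.0, out)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        d = {"family": self.family, "amplitude": self.amplitude}
        for k in ("tau", "tp", "alpha"):
            if getattr(self, k) is not None:
                d[k] = getattr(self, k)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticModel":
        return cls(**dict(d))


def kinetic_value(model: KineticModel, t: float | np.ndarray) -> float | np.ndarray:
    """Functional alias for :meth:`KineticModel.value`."""
    return model.value(t)


def frame_average_curve(
    model: KineticModel, schedule: FrameSchedule, rtol: float = 1e-8
) -> np.ndarray:
    """Frame-wise time averages of C(t): entry i is mean of C over frame i.

    This is what a reconstructed frame measures for a tissue with analytic
    kinetics.  Computed by adaptive quadrature (relative tolerance ``rtol``).
    """
    out = np.empty(schedule.n_frames)
    for i, (a, b) in enumerate(schedule.frames):
        if model.family == "constant":
            out[i] = model.amplitude
            continue
        val, _ = integrate.quad(model.value, a, b, epsrel=rtol, limit=200)
        out[i] = val / (b - a)
    return out


# ---------------------------------------------------------------------------
# Geometric primitives (world coordinates, mm)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def contains(self, zz, yy, xx) -> np.ndarray:
        r2 = (
            (zz - self.center[0]) ** 2
            + (yy - self.center[1]) ** 2
            + (xx - self.center[2]) ** 2
        )
        return r2 <= self.radius**2


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]  # (z, y, x) semi-axes, mm

    def contains(self, zz, yy, xx) -> np.ndarray:
        return (
            ((zz - self.center[0]) / self.semiaxes[0]) ** 2
            + ((yy - self.center[1]) / self.semiaxes[1]) ** 2
            + ((xx - self.center[2]) / self.semiaxes[2]) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned cylinder (default axis z, emulating a vessel segment)."""

    center: tuple[float, float, float]
    radius: float
    half_length: float
    axis: int = 0  # 0=z, 1=y, 2=x

    def contains(self, zz, yy, xx) -> np.ndarray:
        coords = (zz, yy, xx)
        along = np.abs(coords[self.axis] - self.center[self.axis]) <= self.half_length
        others = [a for a in range(3) if a != self.axis]
        r2 = sum((coords[a] - self.center[a]) ** 2 for a in others)
        return along & (r2 <= self.radius**2)


@dataclass(frozen=True)
class EllipsoidShell:
    """Region between two concentric ellipsoids (scalp-like rim)."""

    center: tuple[float, float, float]
    inner_semiaxes: tuple[float, float, float]
    outer_semiaxes: tuple[float, float, float]

    def contains(self, zz, yy, xx) -> np.ndarray:
        outer = Ellipsoid(self.center, self.outer_semiaxes).contains(zz, yy, xx)
        inner = Ellipsoid(self.center, self.inner_semiaxes).contains(zz, yy, xx)
        return outer & ~inner


@dataclass(frozen=True)
class Structure:
    """A named scene element: a shape filled with one kinetic model."""

    name: str
    shape: Sphere | Ellipsoid | Cylinder | EllipsoidShell
    model: KineticModel


# ---------------------------------------------------------------------------
# Phantom specification and construction
# ---------------------------------------------------------------------------

def default_geometry() -> ImageGeometry:
    """Brain-scale but desk-fast grid: 96 x 96 x 64 voxels at 2 mm isotropic."""
    return ImageGeometry(shape=(64, 96, 96), spacing=(2.0, 2.0, 2.0))


@dataclass
class PhantomSpec:
    """Declarative description of one synthetic dynamic scene.

    Structures are painted in order; overlapping voxels raise an error unless
    ``priority`` lists structure names — then the earliest-listed structure
    claims the overlap (deliberate partial-volume scenes).  ``noise_sigma0``
    is the per-voxel SUV noise standard deviation at the 10-min reference
    frame duration; shorter frames are noisier by sqrt(10/duration).
    """

    geometry: ImageGeometry = field(default_factory=default_geometry)
    schedule: FrameSchedule = field(default_factory=FrameSchedule.standard)
    brain: Structure | None = None
    structures: list[Structure] = field(default_factory=list)
    noise_sigma0: float = 0.0
    seed: int = 0
    priority: list[str] | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma0 < 0:
            raise ValueError("noise_sigma0 must be non-negative")
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise ValueError("structure names must be unique")


class OverlapError(ValueError):
    """Two structures claim the same voxels and no priority order was given."""


def build_phantom(
    spec: PhantomSpec, classifier: ClassifierConfig | None = None
) -> tuple[DynamicImage, dict[str, RegionMask], dict[str, str]]:
    """Voxelise a scene into a dynamic image plus ground truth.

    Returns ``(image, truth_masks, truth_labels)``: each voxel's noise-free
    TAC is the frame-averaged curve of its structure's kinetic model;
    ``truth_labels`` holds the three-class pattern of each structure derived
    from its noise-free frame-averaged curve.  Output is fully determined by
    ``spec.seed``.
    """
    geom, sched = spec.geometry, spec.schedule
    zz, yy, xx = geom.meshgrid()
    values = np.zeros((sched.n_frames,) + geom.shape)

    ordered = list(spec.structures)
    if spec.brain is not None:
        ordered = [spec.brain] + ordered

    claimed = np.zeros(geom.shape, dtype=bool)
    truth: dict[str, RegionMask] = {}
    labels: dict[str, str] = {}
    owner_masks: dict[str, np.ndarray] = {}

    # brain is always lowest priority (background tissue)
    non_brain = [s for s in ordered if spec.brain is None or s.name != spec.brain.name]
    for s in non_brain:
        inside = s.shape.contains(zz, yy, xx)
        overlap = inside & claimed
        if overlap.any():
            if spec.priority is None:
                raise OverlapError(
                    f"structure {s.name!r} overlaps an earlier structure; "
                    "give an explicit priority list to allow this"
                )
            for prev_name, prev_mask in owner_masks.items():
                both = inside & prev_mask
                if not both.any():
                    continue
                if spec.priority.index(s.name) < spec.priority.index(prev_name):
                    prev_mask &= ~both  # current structure wins the overlap
                else:
                    inside = inside & ~both
        owner_masks[s.name] = inside.copy()
        claimed |= inside
    if spec.brain is not None:
        brain_inside = spec.brain.shape.contains(zz, yy, xx)
        owner_masks[spec.brain.name] = brain_inside & ~claimed

    for s in ordered:
        mask = owner_masks[s.name]
        curve = frame_average_curve(s.model, sched)
        values[:, mask] = curve[:, None]
        truth[s.name] = RegionMask(np.argwhere(mask), dimensionality=3, definition="MANUAL")
        labels[s.name] = classify_pattern_3(
            TimeActivityCurve(sched.ends, curve), classifier
        )

    if spec.noise_sigma0 > 0:
        rng = np.random.default_rng(spec.seed)
        sigmas = spec.noise_sigma0 / np.sqrt(
            sched.durations / NOISE_REF_DURATION_MIN
        )
        noise = rng.standard_normal(values.shape) * sigmas[:, None, None, None]
        values = values + noise

    return DynamicImage(geom, sched, values), truth, labels


# ---------------------------------------------------------------------------
# Attenuation-correction bias fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasFieldSpec:
    """A time-independent multiplicative bias field standing in for AC error.

    models
        ``uniform``       constant factor ``scale``.
        ``radial``        linear from ``center_scale`` at the volume centre to
                          ``edge_scale`` at the bounding-sphere surface —
                          emulates the centre-vs-skull gradient of missing
                          bone attenuation.
        ``smooth_random`` Gaussian-filtered white noise rescaled to
                          1 +/- ``amplitude`` (correlation length in mm) —
                          emulates spatially varying local bias.
    """

    model: str
    scale: float = 1.0
    center_scale: float = 1.0
    edge_scale: float = 1.0
    correlation_length_mm: float = 20.0
    amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("uniform", "radial", "smooth_random"):
            raise ValueError(f"unknown bias model {self.model!r}")
        if self.model == "uniform" and self.scale <= 0:
            raise ValueError("uniform scale must be positive")
        if self.model == "radial" and (self.center_scale <= 0 or self.edge_scale <= 0):
            raise ValueError("radial scales must be positive")
        if self.model == "smooth_random":
            if not 0 <= self.amplitude < 1:
                raise ValueError("smooth_random amplitude must lie in [0, 1)")
            if self.correlation_length_mm <= 0:
                raise ValueError("correlation length must be positive")


def make_bias_field(spec: BiasFieldSpec, geometry: ImageGeometry) -> np.ndarray:
    """A strictly positive 3D field per the spec, on the given grid."""
    if spec.model == "uniform":
        return np.full(geometry.shape, float(spec.scale))
    zz, yy, xx = geometry.meshgrid()
    if spec.model == "radial":
        cz, cy, cx = geometry.center_world
        r = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
        extent_z = geometry.spacing[0] * (geometry.shape[0] - 1) / 2.0
        extent_y = geometry.spacing[1] * (geometry.shape[1] - 1) / 2.0
        extent_x = geometry.spacing[2] * (geometry.shape[2] - 1) / 2.0
        r_max = math.sqrt(extent_z**2 + extent_y**2 + extent_x**2)
        frac = np.clip(r / r_max, 0.0, 1.0)
        return spec.center_scale + (spec.edge_scale - spec.center_scale) * frac
    # smooth_random
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(geometry.shape)
    sigma_vox = [spec.correlation_length_mm / s for s in geometry.spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.ones(geometry.shape)
    return 1.0 + spec.amplitude * smooth / peak


def apply_bias(img: DynamicImage, bias_field: np.ndarray) -> DynamicImage:
    """Multiply every frame voxelwise by the same 3D field (schedule kept)."""
    bias_field = np.asarray(bias_field, dtype=np.float64)
    if bias_field.shape != img.geometry.shape:
        raise ValueError("bias field shape does not match image geometry")
    if np.any(bias_field <= 0):
        raise ValueError("bias field must be strictly positive")
    return DynamicImage(img.geometry, img.schedule, img.values * bias_field[None])


# ---------------------------------------------------------------------------
# Lightweight TAC-level simulation and scenario helpers
# ---------------------------------------------------------------------------

def simulate_lesion_tac(
    model: KineticModel,
    schedule: FrameSchedule,
    noise_sigma0: float,
    n_voxels: int,
    rng: np.random.Generator,
) -> TimeActivityCurve:
    """A lesion-mean TAC with the phantom's noise model, without voxelising.

    The TAC averages ``n_voxels`` independent voxels, so per-frame noise is
    ``noise_sigma0 / sqrt(duration/10) / sqrt(n_voxels)``.
    """
    curve = frame_average_curve(model, schedule)
    if noise_sigma0 > 0:
        sigmas = noise_sigma0 / np.sqrt(
            schedule.durations / NOISE_REF_DURATION_MIN
        ) / math.sqrt(n_voxels)
        curve = curve + rng.standard_normal(len(curve)) * sigmas
    return TimeActivityCurve(schedule.ends, curve, n_voxels=n_voxels)


def mixed_curve(
    lesion: KineticModel,
    contaminant: KineticModel,
    fraction: float,
    schedule: FrameSchedule,
) -> TimeActivityCurve:
    """TAC of a region mixing lesion and contaminant voxels by volume fraction."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    c = (1.0 - fraction) * frame_average_curve(lesion, schedule) + (
        fraction
    ) * frame_average_curve(contaminant, schedule)
    return TimeActivityCurve(schedule.ends, c)


def vessel_flip_fraction(
    lesion: KineticModel,
    vessel: KineticModel,
    schedule: FrameSchedule | None = None,
    classifier: ClassifierConfig | None = None,
    step: float = 0.01,
) -> float | None:
    """Smallest vessel-volume fraction whose admixture flips the 2-class label.

    Brute-force sweep of the mixed TAC's classification from fraction 0 to 1;
    returns None when no fraction flips an increasing lesion to decreasing.
    Models the segmentation failure mode in which a threshold region spills
    into an adjacent blood vessel with an early-peaking TAC.
    """
    from .kinetics import classify_pattern_2, DECREASING

    schedule = schedule or FrameSchedule.standard()
    for f in np.arange(0.0, 1.0 + step / 2, step):
        tac = mixed_curve(lesion, vessel, float(f), schedule)
        if classify_pattern_2(tac, classifier) == DECREASING:
            return float(f)
    return None


# ---------------------------------------------------------------------------
# Canonical scenes
# ---------------------------------------------------------------------------

def brain_envelope(spec: PhantomSpec) -> RegionMask:
    """All voxels inside the brain shape, regardless of structure ownership.

    The ``brain`` truth mask holds only background-brain voxels (lesions and
    confounders claim theirs); plausibility checks need the full anatomical
    envelope instead.
    """
    if spec.brain is None:
        raise ValueError("spec has no brain structure")
    zz, yy, xx = spec.geometry.meshgrid()
    return RegionMask(
        np.argwhere(spec.brain.shape.contains(zz, yy, xx)),
        dimensionality=3,
        definition="MANUAL",
    )


def brain_structure(
    geometry: ImageGeometry, amplitude: float = 1.0
) -> Structure:
    """An ellipsoidal brain with constant physiological uptake."""
    cz, cy, cx = geometry.center_world
    extent = [geometry.spacing[a] * geometry.shape[a] / 2.0 for a in range(3)]
    semi = tuple(0.85 * e for e in extent)
    return Structure(
        "brain",
        Ellipsoid((cz, cy, cx), semi),
        KineticModel("constant", amplitude=amplitude),
    )


def vessel_scene(
    geometry: ImageGeometry | None = None,
    noise_sigma0: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Increasing lesion abutting an early-peaking vessel (plus brain).

    The vessel keeps enough late activity to exceed the 1.6x-background
    threshold on the summed image, so threshold growing spills into it and
    the mixed TAC picks up the early-peak blood signal.
    """
    geometry = geometry or default_geometry()
    cz, cy, cx = geometry.center_world
    lesion_center = (cz, cy, cx - 20.0)
    vessel_center = (cz, cy, cx - 20.0 + 11.0)
    # slightly hotter core so the uptake maximum sits in the lesion's central
    # axial slice (a perfectly uniform sphere would tie-break to a pole slice)
    core = Structure(
        "lesion_core",
        Sphere(lesion_center, 3.0),
        KineticModel("increasing", amplitude=2.7, tau=10.0),
    )
    lesion = Structure(
        "lesion",
        Sphere(lesion_center, 8.0),
        KineticModel("increasing", amplitude=2.4, tau=10.0),
    )
    vessel = Structure(
        "vessel",
        Cylinder(vessel_center, radius=4.0, half_length=16.0, axis=0),
        KineticModel("gamma_variate", amplitude=12.0, tp=2.0, alpha=0.15),
    )
    return PhantomSpec(
        geometry=geometry,
        brain=brain_structure(geometry),
        structures=[core, lesion, vessel],
        noise_sigma0=noise_sigma0,
        seed=seed,
        priority=["lesion_core", "lesion", "vessel"],
    )


def heterogeneous_lesion_scene(
    geometry: ImageGeometry,
    core_model: KineticModel,
    rim_model: KineticModel,
    center: tuple[float, float, float] | None = None,
    lesion_radius: float = 9.0,
    core_radius: float = 6.0,
    noise_sigma0: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """A two-compartment lesion: a core and a rim with distinct kinetics.

    The core sphere takes priority inside the enclosing lesion sphere, which
    becomes the rim compartment.
    """
    cz, cy, cx = geometry.center_world
    center = center or (cz, cy, cx - 18.0)
    core = Structure("core", Sphere(center, core_radius), core_model)
    rim = Structure("rim", Sphere(center, lesion_radius), rim_model)
    return PhantomSpec(
        geometry=geometry,
        brain=brain_structure(geometry),
        structures=[core, rim],
        noise_sigma0=noise_sigma0,
        seed=seed,
        priority=["core", "rim"],
    )
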