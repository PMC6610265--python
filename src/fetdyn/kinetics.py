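"""Time-activity-curve extraction, time-to-peak, TBR and pattern categorisation.

A time-activity curve (TAC) is the mean SUV over a ROI/VOI per reconstructed
frame, plotted against the time elapsed from injection to the end of the
frame.  Two categorisation schemes are implemented, mirroring the evaluation
approaches established for dynamic [18F]FET PET of gliomas:

* two classes — increasing vs. decreasing (early peak within 20 min followed
  by a descent);
* three classes — increasing, plateau (late maximum followed by a plateau or
  slight descent) and decreasing (early peak followed by a continuous
  descent).

The verbal clinical definitions leave "constantly increasing", "slight
descent" and "continuous descent" unquantified; the rules below make them
operational through two configurable fractions (see :class:`ClassifierConfig`
and docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import DynamicImage, RegionMask, RegionError

logger = logging.getLogger("fetdyn")

INCREASING = "INCREASING"
PLATEAU = "PLATEAU"
DECREASING = "DECREASING"

PATTERN2_LABELS = (INCREASING, DECREASING)
PATTERN3_LABELS = (INCREASING, PLATEAU, DECREASING)


@dataclass(frozen=True)
class ClassifierConfig:
    """Operational parameters of the TAC pattern rules.

    early_peak_cutoff_min
        A peak at or before this time (minutes) counts as "early" (default 20,
        inclusive, matching "within 20 min").
    descent_fraction
        Relative drop from peak to last frame, (max - last)/max, that counts
        as a true descent rather than a plateau (default 0.10).
    increase_tolerance
        How close (relative to the maximum) the last frame must stay to the
        maximum for a late-peaking, still-rising curve to count as increasing
        (default 0.025).
    """

    early_peak_cutoff_min: float = 20.0
    descent_fraction: float = 0.10
    increase_tolerance: float = 0.025

    def __post_init__(self) -> None:
        if self.early_peak_cutoff_min <= 0:
            raise ValueError("early_peak_cutoff_min must be positive")
        for name in ("descent_fraction", "increase_tolerance"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass
class TimeActivityCurve:
    """Mean regional SUV per frame versus frame-end time (minutes)."""

    frame_end_min: np.ndarray
    mean_suv: np.ndarray
    n_voxels: int = 1
    source: RegionMask | None = None

    def __post_init__(self) -> None:
        self.frame_end_min = np.asarray(self.frame_end_min, dtype=np.float64)
        self.mean_suv = np.asarray(self.mean_suv, dtype=np.float64)
        if self.frame_end_min.shape != self.mean_suv.shape:
            raise ValueError("frame times and values differ in length")
        if self.frame_end_min.ndim != 1 or len(self.frame_end_min) == 0:
            raise ValueError("TAC must be a non-empty 1D sequence")
        if np.any(np.diff(self.frame_end_min) <= 0):
            raise ValueError("frame end times must be strictly increasing")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")

    def __len__(self) -> int:
        return len(self.mean_suv)

    def scaled(self, a: float) -> "TimeActivityCurve":
        return TimeActivityCurve(
            self.frame_end_min, self.mean_suv * a, self.n_voxels, self.source
        )


@dataclass
class LesionMetrics:
    """Per-lesion metrics under one ROI/VOI definition."""

    definition: str
    pattern2: str
    pattern3: str
    ttp_frame: int
    ttp_min: float
    tbr: float | None
    volume_ml: float
    tac: TimeActivityCurve | None = None
    warning: str | None = None


def extract_tac(img: DynamicImage, mask: RegionMask) -> TimeActivityCurve:
    """Mean SUV over the mask voxels for every frame, at frame-end times."""
    if mask.is_empty:
        raise RegionError("cannot extract a TAC from an empty mask")
    if (mask.voxels < 0).any() or (
        mask.voxels >= np.array(img.geometry.shape)
    ).any():
        raise RegionError("mask extends outside the image geometry")
    zi, yi, xi = mask.indexer()
    means = img.values[:, zi, yi, xi].mean(axis=1)
    return TimeActivityCurve(
        img.schedule.ends, means, n_voxels=mask.n_voxels, source=mask
    )


def time_to_peak(tac: TimeActivityCurve) -> tuple[int, float]:
    """Earliest frame attaining the maximum, and its frame-end time (min)."""
    i = int(np.argmax(tac.mean_suv))  # argmax returns the earliest maximum
    return i, float(tac.frame_end_min[i])


def tbr(img: DynamicImage, lesion: RegionMask, background: float) -> float:
    """Tissue-to-background ratio in the late 30-40 min frame.

    Mean lesion SUV over the frame(s) covering the last 10 minutes of the
    standard acquisition, divided by the background concentration.
    """
    if background <= 0:
        raise ValueError("background must be positive")
    idx, _ = img.schedule.window_frames(30.0, 40.0)
    zi, yi, xi = lesion.indexer()
    w = img.schedule.durations[idx]
    late = np.average(img.values[idx][:, zi, yi, xi].mean(axis=1), weights=w)
    return float(late / background)


def _descent(tac: TimeActivityCurve) -> float:
    m = float(tac.mean_suv.max())
    if m <= 0:
        return 0.0
    return (m - float(tac.mean_suv[-1])) / m


def classify_pattern_2(
    tac: TimeActivityCurve, cfg: ClassifierConfig | None = None
) -> str:
    """Two-class TAC categorisation: increasing vs. decreasing.

    Decreasing means an early maximum (within the cutoff, default 20 min)
    followed by a genuine descent; everything else is increasing.
    """
    cfg = cfg or ClassifierConfig()
    if len(tac) < 3:
        raise ValueError("pattern categorisation needs at least 3 frames")
    _, ttp_min = time_to_peak(tac)
    if ttp_min <= cfg.early_peak_cutoff_min and _descent(tac) > cfg.descent_fraction:
        return DECREASING
    return INCREASING


def classify_pattern_3(
    tac: TimeActivityCurve, cfg: ClassifierConfig | None = None
) -> str:
    """Three-class TAC categorisation: increasing / plateau / decreasing.

    * decreasing — early peak (within the cutoff) with a descent larger than
      ``descent_fraction``;
    * increasing — the maximum lies in the final frame, or the curve peaks
      late, ends within ``increase_tolerance`` of the maximum and is still
      rising into the last frame;
    * plateau — everything else (late maximum followed by a plateau or slight
      descent).

    A late peak followed by a strong descent has no class in the clinical
    three-class scheme; it is assigned plateau and flagged via the logger.
    """
    cfg = cfg or ClassifierConfig()
    if len(tac) < 3:
        raise ValueError("pattern categorisation needs at least 3 frames")
    ttp_frame, ttp_min = time_to_peak(tac)
    d = _descent(tac)
    early = ttp_min <= cfg.early_peak_cutoff_min
    if early and d > cfg.descent_fraction:
        return DECREASING
    if ttp_frame == len(tac) - 1:
        return INCREASING
    if (
        not early
        and tac.mean_suv[-1] >= (1.0 - cfg.increase_tolerance) * tac.mean_suv.max()
        and tac.mean_suv[-1] >= tac.mean_suv[-2]
    ):
        return INCREASING
    if not early and d > cfg.descent_fraction:
        logger.warning(
            "late peak (%.0f min) with strong descent (%.0f%%): no matching "
            "3-class pattern, assigning PLATEAU",
            ttp_min,
            100 * d,
        )
    return PLATEAU
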