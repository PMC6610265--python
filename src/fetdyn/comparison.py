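"""Cross-attenuation-correction comparison harness.

Runs the full per-lesion evaluation (summed image, all ROI/VOI definitions,
plausibility check, TAC, pattern labels, TTP, TBR, volume) on a reference
reconstruction and on test reconstructions of the same acquisition, detects
per-definition changes relative to the reference, and aggregates them into
change tables: percent of lesions whose TAC category changed, TTP frame
shifts as "changed/evaluated (multiset of |shifts|)", and relative TBR and
volume differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DynamicImage, RegionMask, RegionError, windowed_mean_image
from .kinetics import (
    ClassifierConfig,
    LesionMetrics,
    classify_pattern_2,
    classify_pattern_3,
    extract_tac,
    tbr,
    time_to_peak,
)
from .segmentation import (
    ALL_DEFINITIONS,
    ROI90,
    ROI_TBR,
    SPHERE_MANUAL,
    VOI90,
    VOI_FIX,
    VOI_TBR,
    SeedBelowThresholdError,
    SegmentationConfig,
    background_mean,
    find_max_voxel,
    mirror_across_midsagittal,
    plausibility_check,
    segment_roi90,
    segment_tbr,
    segment_voi90,
    sphere_voi,
)

logger = logging.getLogger("fetdyn")

SUMMED_WINDOW = (20.0, 40.0)


@dataclass
class Excluded:
    """Marker for a definition removed from analysis, with the reason."""

    definition: str
    reason: str


@dataclass
class ChangeRecord:
    """Per-lesion, per-definition change of a test AC method vs the reference."""

    lesion_id: str
    definition: str
    ac_method: str
    excluded: bool = False
    exclusion_reason: str | None = None
    pattern2_changed: bool | None = None
    pattern3_changed: bool | None = None
    delta_ttp_frames: int | None = None
    tbr_rel_diff: float | None = None
    volume_rel_diff: float | None = None


def _metrics_for_mask(
    img: DynamicImage,
    mask: RegionMask,
    background: float | None,
    clf: ClassifierConfig,
) -> LesionMetrics:
    tac = extract_tac(img, mask)
    ttp_frame, ttp_min = time_to_peak(tac)
    return LesionMetrics(
        definition=mask.definition,
        pattern2=classify_pattern_2(tac, clf),
        pattern3=classify_pattern_3(tac, clf),
        ttp_frame=ttp_frame,
        ttp_min=ttp_min,
        tbr=tbr(img, mask, background) if background else None,
        volume_ml=mask.volume_ml(img.geometry),
        tac=tac,
    )


def analyze_lesion(
    img: DynamicImage,
    lesion_hint: RegionMask | np.ndarray | tuple,
    seg: SegmentationConfig | None = None,
    clf: ClassifierConfig | None = None,
    background_center: tuple[int, int, int] | None = None,
    manual_sphere_center: tuple[float, float, float] | None = None,
    brain_mask: RegionMask | np.ndarray | None = None,
    definitions: tuple[str, ...] = ALL_DEFINITIONS,
) -> dict[str, LesionMetrics | Excluded]:
    """Evaluate one lesion under every ROI/VOI definition.

    Pipeline per definition: late summed image -> segmentation -> plausibility
    check -> TAC -> pattern labels, TTP, TBR, volume.  Definitions whose
    segmentation fails or is implausible are returned as :class:`Excluded`.

    ``background_center`` (voxel index) defaults to the lesion maximum
    mirrored across the mid-sagittal plane — the synthetic stand-in for the
    manual contralateral placement used with real data.
    ``manual_sphere_center`` (world mm) additionally evaluates a fixed 1-cm
    sphere (``SPHERE_MANUAL``) at that location.
    """
    if lesion_hint is None:
        raise RegionError("a lesion hint (mask, array or seed) is required")
    if isinstance(lesion_hint, RegionMask) and lesion_hint.is_empty:
        raise RegionError("lesion hint is empty")
    seg = seg or SegmentationConfig()
    clf = clf or ClassifierConfig()
    summed = windowed_mean_image(img, *SUMMED_WINDOW)
    max_voxel = (
        tuple(int(i) for i in lesion_hint)
        if isinstance(lesion_hint, tuple)
        else find_max_voxel(summed, lesion_hint)
    )
    if background_center is None:
        background_center = mirror_across_midsagittal(img.geometry, max_voxel)
    background = background_mean(summed, background_center, config=seg)

    results: dict[str, LesionMetrics | Excluded] = {}

    def run(definition: str, segment) -> None:
        try:
            mask = segment()
        except (SeedBelowThresholdError, RegionError) as exc:
            results[definition] = Excluded(definition, f"segmentation failed: {exc}")
            return
        check = plausibility_check(mask, img.geometry, seg, brain_mask)
        if not check.passed:
            logger.warning("definition %s excluded: %s", definition, check.reason)
            results[definition] = Excluded(definition, check.reason)
            return
        results[definition] = _metrics_for_mask(img, mask, background, clf)

    if ROI90 in definitions:
        run(ROI90, lambda: segment_roi90(summed, max_voxel, seg))
    if VOI90 in definitions:
        run(VOI90, lambda: segment_voi90(summed, max_voxel, seg))
    if ROI_TBR in definitions:
        run(ROI_TBR, lambda: segment_tbr(summed, max_voxel, background, "2d", seg))
    if VOI_TBR in definitions:
        run(VOI_TBR, lambda: segment_tbr(summed, max_voxel, background, "3d", seg))
    if VOI_FIX in definitions:
        run(
            VOI_FIX,
            lambda: sphere_voi(
                img.geometry,
                img.geometry.voxel_to_world(max_voxel),
                seg.fix_diameter_mm,
                definition=VOI_FIX,
            ),
        )
    if manual_sphere_center is not None:
        run(
            SPHERE_MANUAL,
            lambda: sphere_voi(
                img.geometry,
                manual_sphere_center,
                seg.manual_sphere_diameter_mm,
                definition=SPHERE_MANUAL,
            ),
        )
    return results


def compare_to_reference(
    ref: dict[str, LesionMetrics | Excluded],
    test: dict[str, LesionMetrics | Excluded],
    lesion_id: str = "lesion",
    ac_method: str = "test",
) -> list[ChangeRecord]:
    """One change record per definition evaluated on the reference image.

    A definition excluded in either reconstruction yields an excluded record.
    Relative differences are (test - ref)/ref; TTP shift is in frame units.
    """
    records: list[ChangeRecord] = []
    for definition, r in ref.items():
        t = test.get(definition)
        if t is None:
            continue
        rec = ChangeRecord(lesion_id, definition, ac_method)
        if isinstance(r, Excluded) or isinstance(t, Excluded):
            rec.excluded = True
            rec.exclusion_reason = (
                r.reason if isinstance(r, Excluded) else t.reason  # type: ignore[union-attr]
            )
        else:
            rec.pattern2_changed = t.pattern2 != r.pattern2
            rec.pattern3_changed = t.pattern3 != r.pattern3
            rec.delta_ttp_frames = t.ttp_frame - r.ttp_frame
            if r.tbr:
                rec.tbr_rel_diff = (t.tbr - r.tbr) / r.tbr
            rec.volume_rel_diff = (t.volume_ml - r.volume_ml) / r.volume_ml
        records.append(rec)
    return records


def format_ttp_summary(changed_shifts: list[int], n_evaluated: int) -> str:
    """Table-style TTP summary: e.g. ``2/24 (1, 3)`` — two of 24 lesions
    shifted, by one and by three frames."""
    shifts = sorted(abs(s) for s in changed_shifts)
    base = f"{len(shifts)}/{n_evaluated}"
    if shifts:
        base += " (" + ", ".join(str(s) for s in shifts) + ")"
    return base


def aggregate(records: list[ChangeRecord]) -> pd.DataFrame:
    """Summary table per (definition, AC method).

    Columns: number evaluated/excluded, percent of lesions with a 2-class and
    a 3-class pattern change (rounded to whole percent, raw fraction kept),
    TTP summary string plus the |shift| multiset, and mean/min/max relative
    TBR and volume differences.
    """
    if not records:
        raise ValueError("no change records to aggregate")
    rows = []
    df = pd.DataFrame([vars(r) for r in records])
    for (definition, method), grp in df.groupby(["definition", "ac_method"], sort=False):
        ok = grp[~grp["excluded"]]
        n_eval = len(ok)
        n_excl = int(grp["excluded"].sum())
        shifts = [int(s) for s in ok["delta_ttp_frames"] if s != 0]
        p2 = ok["pattern2_changed"].sum() / n_eval if n_eval else np.nan
        p3 = ok["pattern3_changed"].sum() / n_eval if n_eval else np.nan
        rows.append(
            {
                "definition": definition,
                "ac_method": method,
                "n_evaluated": n_eval,
                "n_excluded": n_excl,
                "pattern2_change_pct": int(round(100 * p2)) if n_eval else None,
                "pattern3_change_pct": int(round(100 * p3)) if n_eval else None,
                "pattern2_change_frac": p2,
                "pattern3_change_frac": p3,
                "ttp_summary": format_ttp_summary(shifts, n_eval),
                "ttp_shifts": tuple(sorted(abs(s) for s in shifts)),
                "tbr_rel_diff_mean": ok["tbr_rel_diff"].mean(),
                "tbr_rel_diff_min": ok["tbr_rel_diff"].min(),
                "tbr_rel_diff_max": ok["tbr_rel_diff"].max(),
                "volume_rel_diff_mean": ok["volume_rel_diff"].mean(),
                "volume_rel_diff_min": ok["volume_rel_diff"].min(),
                "volume_rel_diff_max": ok["volume_rel_diff"].max(),
            }
        )
    return pd.DataFrame(rows)


def records_to_frame(records: list[ChangeRecord]) -> pd.DataFrame:
    """Flat machine-readable table of all change records."""
    return pd.DataFrame([vars(r) for r in records])


def metrics_to_row(
    lesion_id: str, ac_method: str, result: LesionMetrics | Excluded
) -> dict:
    """Flatten one per-definition analysis result for the metrics table."""
    if isinstance(result, Excluded):
        return {
            "lesion_id": lesion_id,
            "ac_method": ac_method,
            "definition": result.definition,
            "excluded": True,
            "reason": result.reason,
            "pattern2": None,
            "pattern3": None,
            "ttp_frame": None,
            "ttp_min": None,
            "tbr": None,
            "volume_ml": None,
        }
    return {
        "lesion_id": lesion_id,
        "ac_method": ac_method,
        "definition": result.definition,
        "excluded": False,
        "reason": None,
        "pattern2": result.pattern2,
        "pattern3": result.pattern3,
        "ttp_frame": result.ttp_frame,
        "ttp_min": result.ttp_min,
        "tbr": result.tbr,
        "volume_ml": result.volume_ml,
    }


def records_from_metrics_frame(
    metrics: pd.DataFrame, reference_label: str
) -> list[ChangeRecord]:
    """Rebuild change records from a saved metrics table.

    Pairs each (lesion, definition) row of every non-reference AC method with
    the corresponding reference row; rows excluded on either side become
    excluded records.
    """
    if reference_label not in set(metrics["ac_method"]):
        raise ValueError(f"reference label {reference_label!r} not in metrics")
    records: list[ChangeRecord] = []
    ref = metrics[metrics["ac_method"] == reference_label].set_index(
        ["lesion_id", "definition"]
    )
    for _, row in metrics[metrics["ac_method"] != reference_label].iterrows():
        key = (row["lesion_id"], row["definition"])
        if key not in ref.index:
            continue
        r = ref.loc[key]
        rec = ChangeRecord(row["lesion_id"], row["definition"], row["ac_method"])
        if bool(r["excluded"]) or bool(row["excluded"]):
            rec.excluded = True
            rec.exclusion_reason = r["reason"] if bool(r["excluded"]) else row["reason"]
        else:
            rec.pattern2_changed = row["pattern2"] != r["pattern2"]
            rec.pattern3_changed = row["pattern3"] != r["pattern3"]
            rec.delta_ttp_frames = int(row["ttp_frame"]) - int(r["ttp_frame"])
            if pd.notna(r["tbr"]) and r["tbr"]:
                rec.tbr_rel_diff = (row["tbr"] - r["tbr"]) / r["tbr"]
            rec.volume_rel_diff = (row["volume_ml"] - r["volume_ml"]) / r["volume_ml"]
        records.append(rec)
    return records
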