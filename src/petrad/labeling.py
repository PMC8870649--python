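"""Per-lesion response labeling and delta-radiomics.

A lesion is compared between baseline (T0) and follow-up (T1) on its
longest diameter and SUVmax. Either quantity changing by at least the
threshold (default 25%) triggers the category; progression takes
precedence over reduction when both trigger. Disappearance at T1 is
complete response. The dichotomous outcome codes progression as 0 and any
other category (response) as 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "LesionMeasurement",
    "ResponseLabel",
    "classify_response",
    "dichotomize",
    "delta_feature",
    "delta_table",
    "label_cohort",
]

CATEGORIES = ("PD", "SD", "PR", "CR")
DEFAULT_THRESHOLD_PCT = 25.0


@dataclass(frozen=True)
class LesionMeasurement:
    lesion_id: str
    timepoint: str
    size_mm: float = math.nan
    suv_max: float = math.nan
    present: bool = True

    def __post_init__(self) -> None:
        if self.present:
            if not (self.size_mm > 0):
                raise ValueError(f"{self.lesion_id}: size must be > 0 when lesion present")
            if not (self.suv_max > 0):
                raise ValueError(f"{self.lesion_id}: SUVmax must be > 0 when lesion present")


@dataclass(frozen=True)
class ResponseLabel:
    lesion_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def dichotomous(self) -> int:
        return 0 if self.category == "PD" else 1


def classify_response(
    t0: LesionMeasurement,
    t1: LesionMeasurement,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> ResponseLabel:
    """Assign PD/SD/PR/CR from paired measurements.

    CR if the lesion is absent at T1; PD if size or SUVmax increased by at
    least ``threshold_pct``; PR if either decreased by at least
    ``threshold_pct`` (and no PD trigger); SD otherwise.
    """
    if t0.lesion_id != t1.lesion_id:
        raise ValueError(f"lesion id mismatch: {t0.lesion_id!r} vs {t1.lesion_id!r}")
    if not t0.present:
        raise ValueError(f"{t0.lesion_id}: lesion missing at baseline")
    if not t1.present:
        return ResponseLabel(t0.lesion_id, "CR")
    size_change = 100.0 * (t1.size_mm - t0.size_mm) / t0.size_mm
    suv_change = 100.0 * (t1.suv_max - t0.suv_max) / t0.suv_max
    if size_change >= threshold_pct or suv_change >= threshold_pct:
        return ResponseLabel(t0.lesion_id, "PD")
    if size_change <= -threshold_pct or suv_change <= -threshold_pct:
        return ResponseLabel(t0.lesion_id, "PR")
    return ResponseLabel(t0.lesion_id, "SD")


def dichotomize(label: ResponseLabel | str) -> int:
    """0 for progression, 1 for response (SD, PR or CR)."""
    category = label.category if isinstance(label, ResponseLabel) else label
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return 0 if category == "PD" else 1


def delta_feature(f_t0: float, f_t1: float) -> float:
    """Percent change ``100 * (T1 - T0) / T0``; NaN when T0 is 0."""
    if f_t0 == 0 or not np.isfinite(f_t0) or not np.isfinite(f_t1):
        return math.nan
    return 100.0 * (f_t1 - f_t0) / f_t0


def delta_table(t0: pd.DataFrame, t1: pd.DataFrame) -> pd.DataFrame:
    """Per-lesion percent change for every shared feature column.

    Inputs are wide tables indexed by lesion id. Lesions absent from the
    T1 table (complete responses) are dropped; zero-baseline features are
    NaN.
    """
    common = t0.index.intersection(t1.index)
    cols = [c for c in t0.columns if c in t1.columns]
    t0a = t0.loc[common, cols].astype(float)
    t1a = t1.loc[common, cols].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * (t1a - t0a) / t0a
    return delta.mask(t0a == 0)


def label_cohort(measurements: pd.DataFrame, threshold_pct: float = DEFAULT_THRESHOLD_PCT) -> pd.DataFrame:
    """Label every lesion in a long measurement table.

    Expects columns ``lesion_id, timepoint, size_mm, suv_max, present``;
    lesions with a T0 row are labeled (missing T1 row counts as absent).
    Returns a frame with ``lesion_id, category, dichotomous``.
    """
    rows = []
    for lesion_id, grp in measurements.groupby("lesion_id", sort=True):
        by_tp = {tp: sub.iloc[0] for tp, sub in grp.groupby("timepoint")}
        if "T0" not in by_tp:
            raise ValueError(f"{lesion_id}: no baseline measurement")
        r0 = by_tp["T0"]
        t0 = LesionMeasurement(str(lesion_id), "T0", float(r0["size_mm"]), float(r0["suv_max"]),
                               bool(r0.get("present", True)))
        if "T1" in by_tp:
            r1 = by_tp["T1"]
            present = bool(r1.get("present", True))
            t1 = LesionMeasurement(
                str(lesion_id), "T1",
                float(r1["size_mm"]) if present else math.nan,
                float(r1["suv_max"]) if present else math.nan,
                present,
            )
        else:
            t1 = LesionMeasurement(str(lesion_id), "T1", present=False)
        label = classify_response(t0, t1, threshold_pct)
        rows.append({"lesion_id": lesion_id, "category": label.category,
                     "dichotomous": label.dichotomous})
    return pd.DataFrame(rows)
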