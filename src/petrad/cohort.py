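"""Group-difference testing, per-site sub-analyses, delta summaries and
report tables.

Non-responder vs responder comparisons use the two-sided Mann-Whitney U
test (exact for small tie-free samples, tie-corrected normal approximation
otherwise). Features significant at alpha get a single-feature ROC with a
Youden cut-off; an AUC below 0.5 is flagged "not informative" and the
flipped-orientation complement is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .modeling import ROCResult, roc_curve
from .selection import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "PerSiteResult",
    "mann_whitney",
    "compare_groups",
    "per_site_analysis",
    "delta_group_summary",
    "build_report",
]


@dataclass
class GroupComparison:
    feature: str
    district: str
    n_responder: int
    n_nonresponder: int
    responder_median: float
    responder_mean: float
    responder_sd: float
    responder_range: tuple[float, float]
    nonresponder_median: float
    nonresponder_mean: float
    nonresponder_sd: float
    nonresponder_range: tuple[float, float]
    u_statistic: float
    p_value: float


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_groups(values, labels, feature: str = "", district: str = "all") -> GroupComparison:
    """Responder (label 1) vs non-responder (label 0) summary + U test."""
    x = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels)
    resp = x[y == 1]
    nonresp = x[y == 0]
    if resp.size == 0 or nonresp.size == 0:
        raise ValueError("both classes must be present")
    u, p = mann_whitney(nonresp, resp)
    return GroupComparison(
        feature=feature,
        district=district,
        n_responder=int(resp.size),
        n_nonresponder=int(nonresp.size),
        responder_median=float(np.median(resp)),
        responder_mean=float(resp.mean()),
        responder_sd=float(resp.std(ddof=1)) if resp.size > 1 else 0.0,
        responder_range=(float(resp.min()), float(resp.max())),
        nonresponder_median=float(np.median(nonresp)),
        nonresponder_mean=float(nonresp.mean()),
        nonresponder_sd=float(nonresp.std(ddof=1)) if nonresp.size > 1 else 0.0,
        nonresponder_range=(float(nonresp.min()), float(nonresp.max())),
        u_statistic=u,
        p_value=p,
    )


@dataclass
class PerSiteResult:
    district: str
    comparisons: list[GroupComparison]
    roc_by_feature: dict[str, ROCResult]
    not_informative: dict[str, float]  # feature -> flipped-orientation AUC complement


def per_site_analysis(table: FeatureTable, district: str, alpha: float = 0.05) -> PerSiteResult:
    """Test every feature within one district and ROC the significant ones.

    Single-feature ROCs use the raw feature as score with the
    non-responder as positive class, without reorientation, so that an
    inverted feature shows up as AUC < 0.5 and is flagged not informative
    (the flipped complement 1 - AUC is recorded separately).
    """
    if table.district is None:
        raise ValueError("table has no district column")
    mask = table.district == district
    if not mask.any():
        raise ValueError(f"no lesions in district {district!r}")
    sub = table.subset(mask)
    comparisons = []
    roc_by_feature: dict[str, ROCResult] = {}
    not_informative: dict[str, float] = {}
    for feature in sub.features.columns:
        vals = sub.features[feature].to_numpy(dtype=np.float64)
        finite = np.isfinite(vals)
        if finite.sum() < 4 or len(np.unique(sub.labels[finite])) < 2:
            logger.warning("%s/%s: insufficient data, skipped", district, feature)
            continue
        comp = compare_groups(vals[finite], sub.labels[finite], feature, district)
        comparisons.append(comp)
        if comp.p_value < alpha:
            roc = roc_curve(vals[finite], sub.labels[finite].to_numpy(), positive_label=0)
            roc_by_feature[feature] = roc
            if roc.auc < 0.5:
                not_informative[feature] = 1.0 - roc.auc
    return PerSiteResult(district, comparisons, roc_by_feature, not_informative)


def delta_group_summary(deltas: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-feature group mean, SD and range of percent changes, plus the
    Mann-Whitney p-value between responders and non-responders.

    ``deltas`` is a wide lesion x feature table of percent changes; rows
    with missing values are excluded pairwise per feature.
    """
    y = pd.Series(np.asarray(labels), index=deltas.index).astype(int)
    rows = []
    for feature in deltas.columns:
        d = deltas[feature].astype(float)
        ok = d.notna()
        resp = d[ok & (y == 1)]
        nonresp = d[ok & (y == 0)]
        if resp.empty or nonresp.empty:
            raise ValueError(f"{feature}: a group has no finite delta values")
        _, p = mann_whitney(nonresp, resp)
        rows.append(
            {
                "feature": feature,
                "responder_mean": resp.mean(),
                "responder_sd": resp.std(ddof=1) if len(resp) > 1 else 0.0,
                "responder_min": resp.min(),
                "responder_max": resp.max(),
                "responder_n": len(resp),
                "nonresponder_mean": nonresp.mean(),
                "nonresponder_sd": nonresp.std(ddof=1) if len(nonresp) > 1 else 0.0,
                "nonresponder_min": nonresp.min(),
                "nonresponder_max": nonresp.max(),
                "nonresponder_n": len(nonresp),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def _comparison_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "district": c.district,
                "feature": c.feature,
                "responder_n": c.n_responder,
                "responder_median": c.responder_median,
                "responder_mean": c.responder_mean,
                "responder_sd": c.responder_sd,
                "responder_min": c.responder_range[0],
                "responder_max": c.responder_range[1],
                "nonresponder_n": c.n_nonresponder,
                "nonresponder_median": c.nonresponder_median,
                "nonresponder_mean": c.nonresponder_mean,
                "nonresponder_sd": c.nonresponder_sd,
                "nonresponder_min": c.nonresponder_range[0],
                "nonresponder_max": c.nonresponder_range[1],
                "u_statistic": c.u_statistic,
                "p_value": c.p_value,
            }
        )
    return pd.DataFrame(rows)


def build_report(
    labels: pd.Series,
    districts: pd.Series,
    per_site: list[PerSiteResult] | None = None,
    delta_summaries: dict[str, pd.DataFrame] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble cohort-level summary tables.

    Returns a dict of deterministic DataFrames: a cohort summary (lesion
    counts per district and per outcome), a per-district comparison table
    and a per-district delta table. Raises on an empty cohort.
    """
    labels = pd.Series(labels)
    districts = pd.Series(np.asarray(districts), index=labels.index)
    if labels.empty:
        raise ValueError("empty cohort: nothing to report")
    n = len(labels)
    district_counts = districts.value_counts().sort_index()
    rows = [
        {"section": "total", "item": "lesions", "count": n, "fraction": 1.0},
    ]
    for d, c in district_counts.items():
        rows.append({"section": "district", "item": d, "count": int(c), "fraction": c / n})
    for cls, name in ((0, "non_responder"), (1, "responder")):
        c = int((labels == cls).sum())
        rows.append({"section": "outcome", "item": name, "count": c, "fraction": c / n})
    cohort = pd.DataFrame(rows)

    report: dict[str, pd.DataFrame] = {"cohort_summary": cohort}
    if per_site:
        report["district_comparisons"] = pd.concat(
            [_comparison_frame(ps.comparisons) for ps in per_site], ignore_index=True
        )
        roc_rows = []
        for ps in per_site:
            for feature, roc in sorted(ps.roc_by_feature.items()):
                roc_rows.append(
                    {
                        "district": ps.district,
                        "feature": feature,
                        "auc": roc.auc,
                        "youden_cutoff": roc.youden_cutoff,
                        "sensitivity": roc.sens_at_cutoff,
                        "specificity": roc.spec_at_cutoff,
                        "not_informative": feature in ps.not_informative,
                        "flipped_auc": ps.not_informative.get(feature, np.nan),
                    }
                )
        report["district_rocs"] = pd.DataFrame(roc_rows)
    if delta_summaries:
        frames = []
        for district, summary in sorted(delta_summaries.items()):
            s = summary.reset_index()
            s.insert(0, "district", district)
            frames.append(s)
        report["delta_summary"] = pd.concat(frames, ignore_index=True)
    return report
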