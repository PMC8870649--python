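"""Machine-readable copies of the published source-cohort summary tables.

These printed values (lesion counts, per-district responder /
non-responder location-scale summaries, delta-radiomics summaries and
reported ROC operating points) are embedded as fixtures: they calibrate
the surrogate simulations and anchor report-validation tests. The
original per-lesion data are not publicly deposited.
"""

from __future__ import annotations

__all__ = [
    "cohort_counts",
    "district_group_sizes",
    "district_summaries",
    "delta_summaries",
    "reported_roc",
    "reference_fixtures",
]

#: lesion counts by district and by response category (whole cohort)
COHORT_COUNTS = {
    "districts": {"liver": 169, "lymph_node": 91, "bone": 42, "parenchymal_other": 22},
    "response_categories": {"PD": 133, "SD": 79, "PR": 92, "CR": 20},
    # responsive lesions / total lesions per grading class
    "grading_response": {"G1": (28, 82), "G2": (157, 232), "G3": (6, 10)},
    "n_patients": 38,
}

#: (n_responders, n_non_responders) per district sub-analysis
DISTRICT_GROUP_SIZES = {
    "lymph_node": (50, 41),
    "liver": (108, 61),
    "bone": (18, 24),
}

#: per-district (location, scale) summaries: {district: {feature:
#: {"responder": (loc, scale), "non_responder": (loc, scale)}}}
DISTRICT_SUMMARIES = {
    "lymph_node": {
        "HISTO_Skewness": {"responder": (2.01, 2.12), "non_responder": (3.02, 1.44)},
        "HISTO_Kurtosis": {"responder": (11.03, 11.79), "non_responder": (13.72, 8.85)},
        "SUV_max": {"responder": (18.67, 12.14), "non_responder": (18.16, 13.86)},
    },
    "liver": {
        "HISTO_Skewness": {"responder": (1.35, 2.25), "non_responder": (3.63, 1.90)},
        "HISTO_Kurtosis": {"responder": (9.04, 11.90), "non_responder": (19.34, 13.86)},
        "SUV_max": {"responder": (19.39, 10.17), "non_responder": (20.87, 10.14)},
    },
    "bone": {
        "HISTO_Skewness": {"responder": (2.40, 1.89), "non_responder": (4.03, 1.87)},
        "HISTO_Kurtosis": {"responder": (11.57, 12.83), "non_responder": (23.13, 15.46)},
        "SUV_max": {"responder": (10.31, 9.41), "non_responder": (28.42, 28.61)},
    },
}

#: per-district percent-change (mean, sd) summaries for the delta analysis
DELTA_SUMMARIES = {
    "lymph_node": {
        "HISTO_Skewness": {"responder": (21.18, 265.75), "non_responder": (176.83, 469.34)},
        "HISTO_Kurtosis": {"responder": (13.97, 83.08), "non_responder": (-4.48, 40.84)},
    },
    "liver": {
        "HISTO_Skewness": {"responder": (-17.72, 865.36), "non_responder": (134.23, 324.32)},
        "HISTO_Kurtosis": {"responder": (9.76, 52.45), "non_responder": (14.64, 60.64)},
    },
    "bone": {
        "HISTO_Skewness": {"responder": (6.84, 70.95), "non_responder": (-24.54, 71.06)},
        "HISTO_Kurtosis": {"responder": (66.15, 113.10), "non_responder": (-0.33, 41.43)},
    },
}

#: reported single-feature ROC operating points; sensitivity/specificity
#: in percent, whole cohort unless a district is given
REPORTED_ROC = {
    ("all", "HISTO_Skewness"): {"auc": 0.745, "cutoff": 2.45, "sens": 80.6, "spec": 67.2},
    ("all", "HISTO_Kurtosis"): {"auc": 0.722, "cutoff": 6.94, "sens": 61.2, "spec": 75.9},
    ("all", "SUV_max"): {"auc": 0.523, "cutoff": None, "sens": 36.7, "spec": 63.3},
    ("all", "combined_skew_kurt_grading"): {"auc": 0.744, "cutoff": None, "sens": 66.4, "spec": 70.3},
    ("lymph_node", "HISTO_Skewness"): {"auc": 0.67, "cutoff": 2.45, "sens": 76.0, "spec": 60.0},
    ("lymph_node", "HISTO_Kurtosis"): {"auc": 0.64, "cutoff": 8.10, "sens": 76.0, "spec": 58.0},
    ("liver", "HISTO_Skewness"): {"auc": 0.76, "cutoff": 1.94, "sens": 87.0, "spec": 67.0},
    ("liver", "HISTO_Kurtosis"): {"auc": 0.75, "cutoff": 6.55, "sens": 87.0, "spec": 68.0},
    ("bone", "HISTO_Skewness"): {"auc": 0.73, "cutoff": 3.33, "sens": 79.0, "spec": 78.0},
    ("bone", "HISTO_Kurtosis"): {"auc": 0.72, "cutoff": 15.33, "sens": 79.0, "spec": 78.0},
}


def cohort_counts() -> dict:
    return {k: dict(v) if isinstance(v, dict) else v for k, v in COHORT_COUNTS.items()}


def district_group_sizes() -> dict[str, tuple[int, int]]:
    return dict(DISTRICT_GROUP_SIZES)


def district_summaries() -> dict:
    return {d: {f: dict(g) for f, g in feats.items()} for d, feats in DISTRICT_SUMMARIES.items()}


def delta_summaries() -> dict:
    return {d: {f: dict(g) for f, g in feats.items()} for d, feats in DELTA_SUMMARIES.items()}


def reported_roc() -> dict:
    return {k: dict(v) for k, v in REPORTED_ROC.items()}


def reference_fixtures() -> dict:
    """All embedded reference tables in one bundle."""
    return {
        "cohort_counts": cohort_counts(),
        "district_group_sizes": district_group_sizes(),
        "district_summaries": district_summaries(),
        "delta_summaries": delta_summaries(),
        "reported_roc": reported_roc(),
    }
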