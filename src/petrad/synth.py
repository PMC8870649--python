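"""Synthetic inputs for the pipeline.

Three generators are provided: voxel-level ellipsoidal lesions with
moment-matched intensity distributions, per-district feature cohorts
drawn from the published location-scale summaries (plus uninformative
noise features), and paired baseline/follow-up cohorts with injected
per-group percent changes. All generators are deterministic for a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

from . import fixtures
from .fixtures import reference_fixtures  # re-exported convenience
from .imaging import LesionROI, PETVolume
from .modeling import roc_curve
from .selection import FeatureTable

__all__ = [
    "GroupLocScale",
    "DistrictParams",
    "CohortSpec",
    "LesionSpec",
    "table2_params",
    "sample_feature_cohort",
    "synth_lesion_volume",
    "sample_paired_cohort",
    "surrogate_single_feature_auc",
    "analytic_two_gaussian_auc",
    "reference_fixtures",
]

INFORMATIVE_FEATURES = ("HISTO_Skewness", "HISTO_Kurtosis", "SUV_max")


@dataclass(frozen=True)
class GroupLocScale:
    responder: tuple[float, float]
    non_responder: tuple[float, float]

    def __post_init__(self) -> None:
        for loc, scale in (self.responder, self.non_responder):
            if scale <= 0:
                raise ValueError(f"scale must be positive, got {scale}")


@dataclass(frozen=True)
class DistrictParams:
    """Per-district group sizes and per-feature location-scale parameters."""

    district: str
    n_responders: int
    n_non_responders: int
    features: dict[str, GroupLocScale]

    def __post_init__(self) -> None:
        if self.n_responders < 2 or self.n_non_responders < 2:
            raise ValueError("each group needs >= 2 lesions")


def table2_params() -> dict[str, DistrictParams]:
    """Published per-district summaries as simulation parameters.

    Location-scale pairs for HISTO_Skewness, HISTO_Kurtosis and SUV_max
    in the lymph-node (50/41), liver (108/61) and bone (18/24) districts,
    treated as normal mean/SD for the surrogate cohorts.
    """
    sizes = fixtures.district_group_sizes()
    summaries = fixtures.district_summaries()
    out = {}
    for district, feats in summaries.items():
        n_resp, n_nonresp = sizes[district]
        out[district] = DistrictParams(
            district=district,
            n_responders=n_resp,
            n_non_responders=n_nonresp,
            features={
                name: GroupLocScale(tuple(g["responder"]), tuple(g["non_responder"]))
                for name, g in feats.items()
            },
        )
    return out


@dataclass
class CohortSpec:
    """Specification of a surrogate feature cohort."""

    districts: dict[str, DistrictParams] = field(default_factory=table2_params)
    n_noise_features: int = 0
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("correlation must lie in (-1, 1)")
        if self.n_noise_features < 0:
            raise ValueError("n_noise_features must be >= 0")


def _draw_group(rng, params: DistrictParams, group: str, n: int, corr: float) -> pd.DataFrame:
    names = list(params.features)
    locs = np.array([getattr(params.features[f], group)[0] for f in names])
    scales = np.array([getattr(params.features[f], group)[1] for f in names])
    k = len(names)
    if corr == 0.0 or k == 1:
        z = rng.standard_normal((n, k))
    else:
        cov = np.full((k, k), corr)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    return pd.DataFrame(locs + scales * z, columns=names)


def sample_feature_cohort(spec: CohortSpec) -> FeatureTable:
    """Draw a labeled per-district feature cohort.

    Informative features come from per-group normal distributions with
    the specified location/scale; noise features are standard normal and
    independent of the outcome. Labels code responders as 1.
    """
    rng = np.random.default_rng(spec.seed)
    frames, labels, districts = [], [], []
    for district in sorted(spec.districts):
        params = spec.districts[district]
        for group, lab, n in (
            ("responder", 1, params.n_responders),
            ("non_responder", 0, params.n_non_responders),
        ):
            frames.append(_draw_group(rng, params, group, n, spec.correlation))
            labels.extend([lab] * n)
            districts.extend([district] * n)
    features = pd.concat(frames, ignore_index=True)
    if spec.n_noise_features:
        noise = pd.DataFrame(
            rng.standard_normal((len(features), spec.n_noise_features)),
            columns=[f"NOISE_{i:03d}" for i in range(spec.n_noise_features)],
        )
        features = pd.concat([features, noise], axis=1)
    features.index = [f"lesion_{i:04d}" for i in range(len(features))]
    return FeatureTable(
        features=features,
        labels=pd.Series(labels, index=features.index),
        district=pd.Series(districts, index=features.index),
    )


@dataclass(frozen=True)
class LesionSpec:
    """Target geometry and intensity moments for one synthetic lesion."""

    n_voxels: int = 1000
    mean_suv: float = 10.0
    sd_suv: float | None = None  # default mean/4
    skewness: float = 0.0
    kurtosis: float | None = None  # feasibility check only
    semi_axes: tuple[float, float, float] | None = None
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.mean_suv <= 0:
            raise ValueError("mean_suv must be positive")
        if self.kurtosis is not None and self.kurtosis < self.skewness**2 + 1:
            raise ValueError("infeasible moments: kurtosis < skewness^2 + 1")


def _lognormal_sigma(skew: float) -> float:
    """Shape parameter of a lognormal with the given (positive) skewness."""
    f = lambda w: (w + 2.0) * math.sqrt(w - 1.0) - skew
    w = optimize.brentq(f, 1.0 + 1e-12, 1e6)
    return math.sqrt(math.log(w))


def _standardized_skewed(rng, n: int, skew: float) -> np.ndarray:
    """Zero-mean unit-SD values with the requested skewness sign/magnitude.

    Uses mid-point plotting-position quantiles of the moment-matched
    distribution (lognormal for skewed targets, normal otherwise) rather
    than iid draws, so the achieved sample moments are deterministic and
    tight even at moderate voxel counts; spatial randomness comes from a
    seeded permutation.
    """
    q = (np.arange(n) + 0.5) / n
    if abs(skew) < 1e-8:
        z = sstats.norm.ppf(q)
    else:
        sigma = _lognormal_sigma(abs(skew))
        z = sstats.lognorm.ppf(q, s=sigma)
    z = (z - z.mean()) / z.std() if n > 1 else np.zeros(1)
    if skew < 0:
        z = -z
    rng.shuffle(z)
    return z


def synth_lesion_volume(
    spec: LesionSpec, seed: int = 0, upper_clip: float = 60.0
) -> tuple[PETVolume, LesionROI]:
    """Build an ellipsoidal lesion in a zero background.

    The mask contains exactly ``n_voxels`` voxels (those closest to the
    center in the ellipsoid norm, lexicographic tie-break). Intensities
    are drawn from a moment-matched shifted lognormal (normal when the
    target skewness is ~0), clipped to ``[0, upper_clip)``.
    """
    rng = np.random.default_rng(seed)
    if spec.semi_axes is None:
        r = max(1.5, (3.0 * spec.n_voxels / (4.0 * math.pi)) ** (1.0 / 3.0) + 1.0)
        axes = (r, r, r)
    else:
        axes = spec.semi_axes
    half = tuple(int(math.ceil(a)) + 1 for a in axes)
    shape = tuple(2 * h + 1 for h in half)
    grids = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
    r2 = sum((g / a) ** 2 for g, a in zip(grids, axes))
    flat = r2.ravel()
    if spec.n_voxels > flat.size:
        raise ValueError("semi-axes bounding box too small for n_voxels")
    order = np.lexsort((np.arange(flat.size), flat))
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[: spec.n_voxels]] = True
    mask = mask.reshape(shape)

    sd = spec.sd_suv if spec.sd_suv is not None else spec.mean_suv / 4.0
    z = _standardized_skewed(rng, spec.n_voxels, spec.skewness)
    # shrink the spread if needed so the affine map stays inside the clip
    # range (clipping would distort the matched moments)
    if z.min() < 0:
        sd = min(sd, 0.999 * spec.mean_suv / -z.min())
    if z.max() > 0:
        sd = min(sd, 0.999 * (upper_clip - spec.mean_suv) / z.max())
    intensities = np.clip(spec.mean_suv + sd * z, 0.0, np.nextafter(upper_clip, 0.0))
    voxels = np.zeros(shape)
    voxels[mask] = intensities
    volume = PETVolume(voxels=voxels, spacing=spec.spacing)
    roi = LesionROI(mask=mask, lesion_id=f"synthetic_{seed}")
    return volume, roi


def sample_paired_cohort(
    spec: CohortSpec,
    delta_params: dict[str, dict[str, dict[str, tuple[float, float]]]] | None = None,
) -> tuple[FeatureTable, pd.DataFrame, pd.DataFrame]:
    """Draw a baseline cohort plus a follow-up table with injected deltas.

    ``delta_params[district][feature][group]`` gives the (mean, sd) of the
    percent change for that group (default: the published delta table).
    Follow-up values are ``T0 * (1 + delta/100)``; features without delta
    parameters carry over unchanged. Returns the baseline table, the
    follow-up feature frame, and the drawn per-lesion deltas.
    """
    if delta_params is None:
        delta_params = fixtures.delta_summaries()
    t0 = sample_feature_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1)
    deltas = pd.DataFrame(0.0, index=t0.features.index, columns=t0.features.columns)
    for district, feats in delta_params.items():
        in_district = (
            t0.district == district if t0.district is not None else pd.Series(False, index=t0.features.index)
        )
        for feature, groups in feats.items():
            if feature not in deltas.columns:
                continue
            for group, lab in (("responder", 1), ("non_responder", 0)):
                mean, sd = groups[group]
                if sd < 0:
                    raise ValueError("delta sd must be >= 0")
                rows = in_district & (t0.labels == lab)
                k = int(rows.sum())
                if k:
                    deltas.loc[rows, feature] = mean + sd * rng.standard_normal(k)
    t1 = t0.features * (1.0 + deltas / 100.0)
    return t0, t1, deltas


def analytic_two_gaussian_auc(district: str, feature: str) -> float:
    """Closed-form AUC of a single normal feature between the two groups.

    For groups N(mu1, s1) and N(mu0, s0) the probability that a random
    non-responder value exceeds a random responder value is
    ``Phi((mu0 - mu1) / sqrt(s0^2 + s1^2))``.
    """
    g = fixtures.district_summaries()[district][feature]
    mu1, s1 = g["responder"]
    mu0, s0 = g["non_responder"]
    return float(sstats.norm.cdf((mu0 - mu1) / math.hypot(s0, s1)))


def surrogate_single_feature_auc(
    district: str,
    feature: str,
    n_replicates: int = 2000,
    seed: int = 0,
    group_sizes: tuple[int, int] | None = None,
) -> float:
    """Mean empirical single-feature AUC over seeded surrogate cohorts.

    Each replicate draws responder and non-responder values from the
    published district summaries (group sizes from the sub-analysis
    counts) and computes the empirical AUC with non-responder as the
    positive class and the raw feature as the score.
    """
    g = fixtures.district_summaries()[district][feature]
    mu1, s1 = g["responder"]
    mu0, s0 = g["non_responder"]
    if group_sizes is None:
        group_sizes = fixtures.district_group_sizes()[district]
    n_resp, n_nonresp = group_sizes
    rng = np.random.default_rng(seed)
    labels = np.r_[np.ones(n_resp, dtype=int), np.zeros(n_nonresp, dtype=int)]
    aucs = np.empty(n_replicates)
    for i in range(n_replicates):
        vals = np.r_[
            mu1 + s1 * rng.standard_normal(n_resp),
            mu0 + s0 * rng.standard_normal(n_nonresp),
        ]
        aucs[i] = roc_curve(vals, labels, positive_label=0).auc
    return float(aucs.mean())
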