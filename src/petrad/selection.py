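"""Descriptive-inferential feature reduction.

Features are ranked by point-biserial correlation with the dichotomous
outcome, then added one at a time to a logistic model; iteration stops the
first time the model p-value grows, and the retained set is the prefix of
the ranking fitted at the best step.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

logger = logging.getLogger(__name__)

__all__ = [
    "CLINICAL_FEATURES",
    "FeatureTable",
    "SelectionStep",
    "SelectionResult",
    "point_biserial",
    "rank_features",
    "forward_select",
    "prepare_clinical",
]

CLINICAL_FEATURES = (
    "Grading",
    "PRRT_cycles",
    "cumulative_activity_GBq",
    "CgA_pre",
    "CgA_post",
)


@dataclass
class FeatureTable:
    """Wide per-lesion feature matrix with a 0/1 outcome.

    ``features`` holds one row per lesion; ``labels`` codes 1 for response
    and 0 for progression. Columns entering selection must be complete.
    """

    features: pd.DataFrame
    labels: pd.Series
    district: pd.Series | None = None
    patient_id: pd.Series | None = None

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, index=self.features.index).astype(int)
        uniq = set(self.labels.unique())
        if not uniq <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {sorted(uniq)}")
        for cls in (0, 1):
            if (self.labels == cls).sum() < 2:
                raise ValueError(f"need >= 2 rows of class {cls}")
        if self.district is not None:
            self.district = pd.Series(self.district, index=self.features.index)
        if self.patient_id is not None:
            self.patient_id = pd.Series(self.patient_id, index=self.features.index)

    @property
    def n(self) -> int:
        return len(self.features)

    def subset(self, row_mask) -> "FeatureTable":
        return FeatureTable(
            features=self.features.loc[row_mask],
            labels=self.labels.loc[row_mask],
            district=None if self.district is None else self.district.loc[row_mask],
            patient_id=None if self.patient_id is None else self.patient_id.loc[row_mask],
        )


@dataclass
class SelectionStep:
    features: tuple[str, ...]
    p_value: float
    converged: bool
    method: str
    coef_p_values: tuple[float, ...] = ()


@dataclass
class SelectionResult:
    ranking: list[tuple[str, float]]
    dropped: dict[str, str]
    steps: list[SelectionStep]
    retained: tuple[str, ...]
    stop_index: int

    def to_dict(self) -> dict:
        return {
            "ranking": [{"feature": f, "pbc": c} for f, c in self.ranking],
            "dropped": self.dropped,
            "steps": [
                {
                    "features": list(s.features),
                    "p_value": s.p_value,
                    "converged": s.converged,
                    "method": s.method,
                    "coef_p_values": list(s.coef_p_values),
                }
                for s in self.steps
            ],
            "retained": list(self.retained),
            "stop_index": self.stop_index,
        }


def point_biserial(feature, labels) -> float:
    """Pearson correlation between a numeric feature and a 0/1 outcome."""
    x = np.asarray(feature, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("feature and labels differ in length")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature contains missing values")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("feature has zero variance")
    return float(xc @ yc) / denom


def rank_features(
    table: FeatureTable, sort_mode: str = "abs"
) -> tuple[list[tuple[str, float]], dict[str, str]]:
    """Order features by point-biserial correlation.

    ``sort_mode="abs"`` (default) sorts by |pbc| descending, ``"signed"``
    by the signed value descending; ties break lexicographically by name.
    Features with undefined pbc are dropped with a reason.
    """
    if sort_mode not in ("abs", "signed"):
        raise ValueError(f"unknown sort_mode {sort_mode!r}")
    scored: list[tuple[str, float]] = []
    dropped: dict[str, str] = {}
    for name in table.features.columns:
        try:
            scored.append((name, point_biserial(table.features[name], table.labels)))
        except ValueError as exc:
            dropped[name] = str(exc)
            logger.warning("feature %s excluded from ranking: %s", name, exc)
    key = (lambda fc: (-abs(fc[1]), fc[0])) if sort_mode == "abs" else (lambda fc: (-fc[1], fc[0]))
    return sorted(scored, key=key), dropped


def _logit_p_value(X: np.ndarray, y: np.ndarray) -> tuple[float, bool, str, tuple[float, ...]]:
    """Likelihood-ratio p-value of a logistic model vs the intercept-only model.

    Falls back to a lightly ridge-penalized fit when maximum likelihood
    fails (perfect separation, singular Hessian) so that a separating
    feature still yields a near-zero p-value.
    """
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False) and np.isfinite(res.llr_pvalue):
            return float(res.llr_pvalue), True, "mle", tuple(np.asarray(res.pvalues)[1:])
    except Exception as exc:  # LinAlgError, PerfectSeparationError, ...
        logger.warning("logit MLE failed (%s); using penalized fallback", exc)
    # penalized fallback: LRT from ridge log-likelihoods, chi2 with k df
    from sklearn.linear_model import LogisticRegression

    try:
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(X, y)
        eta = X @ clf.coef_.ravel() + clf.intercept_[0]
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        p1 = y.mean()
        ll0 = float(len(y) * (p1 * math.log(p1) + (1 - p1) * math.log(1 - p1)))
        llr = max(0.0, 2.0 * (ll - ll0))
        p = float(sstats.chi2.sf(llr, df=X.shape[1]))
        return p, False, "penalized", ()
    except Exception as exc:
        logger.warning("penalized logit fallback failed: %s", exc)
        return math.nan, False, "failed", ()


def forward_select(
    table: FeatureTable,
    sort_mode: str = "abs",
    p_value_mode: str = "lrt",
    max_features: int | None = None,
) -> SelectionResult:
    """Rank by pbc, then add one feature per step to a logistic model.

    The monitored p-value is the model-vs-intercept likelihood-ratio
    p-value (``p_value_mode="lrt"``) or the Wald p-value of the newest
    coefficient (``"coef"``). The loop stops the first time the p-value
    exceeds the previous step's; a step whose fit fails outright is
    treated the same way. The retained set is the ranking prefix of the
    last accepted step.
    """
    if p_value_mode not in ("lrt", "coef"):
        raise ValueError(f"unknown p_value_mode {p_value_mode!r}")
    ranking, dropped = rank_features(table, sort_mode=sort_mode)
    names = [f for f, _ in ranking]
    if max_features is not None:
        names = names[:max_features]
    y = table.labels.to_numpy(dtype=np.float64)
    steps: list[SelectionStep] = []
    best_p = math.inf
    retained: tuple[str, ...] = ()
    stop_index = 0
    for k, _name in enumerate(names, start=1):
        cols = names[:k]
        X = table.features[cols].to_numpy(dtype=np.float64)
        p_lrt, converged, method, coef_ps = _logit_p_value(X, y)
        p = p_lrt if p_value_mode == "lrt" else (coef_ps[-1] if coef_ps else p_lrt)
        steps.append(SelectionStep(tuple(cols), p, converged, method, coef_ps))
        if method == "failed" or not np.isfinite(p) or p > best_p:
            stop_index = k
            break
        best_p = p
        retained = tuple(cols)
        stop_index = k
    return SelectionResult(
        ranking=ranking, dropped=dropped, steps=steps, retained=retained, stop_index=stop_index
    )


def prepare_clinical(df: pd.DataFrame, include_cga_post: bool = False) -> pd.DataFrame:
    """Transform clinical columns for modeling.

    Grading G1/G2/G3 becomes ordinal 1/2/3; CgA values are log-transformed
    (right-skewed lab values). ``CgA_post`` post-dates therapy and is
    excluded from the default predictor set.
    """
    out = df.copy()
    if "Grading" in out:
        grading = out["Grading"]
        if grading.dtype == object:
            out["Grading"] = grading.map({"G1": 1, "G2": 2, "G3": 3}).astype(float)
        else:
            out["Grading"] = grading.astype(float)
    for col in ("CgA_pre", "CgA_post"):
        if col in out:
            vals = out[col].astype(float)
            if (vals <= 0).any():
                raise ValueError(f"{col}: log transform requires positive values")
            out[col] = np.log(vals)
    if not include_cga_post and "CgA_post" in out:
        out = out.drop(columns=["CgA_post"])
    return out
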