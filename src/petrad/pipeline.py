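"""End-to-end pipeline: select -> cross-validate -> ROC/Youden -> delta ->
per-site -> report, with provenance (config hash + seed) on every output.

Every stage is a pure function of (inputs, config, seed); reruns with the
same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, labeling, modeling, selection, synth
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "nested_cv_scores", "load_feature_table", "extract_cohort"]

_FLOAT_FMT = "%.10g"


def extract_cohort(metadata_csv, hist_cfg=None, glcm_cfg=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract features for every lesion listed in a metadata CSV.

    The CSV needs columns ``lesion_id, patient_id, district, timepoint,
    volume_path, mask_path``. Lesions failing the ROI inclusion rule are
    skipped with a logged reason. Returns the wide feature frame and a
    log frame of skipped lesions.
    """
    from . import features as feat
    from . import imaging

    hist_cfg = hist_cfg or imaging.DiscretizationConfig()
    glcm_cfg = glcm_cfg or feat.GLCMConfig()
    meta = pd.read_csv(metadata_csv)
    required = {"lesion_id", "volume_path", "mask_path"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata CSV must have columns {sorted(required)}")
    rows, skipped = {}, []
    for _, rec in meta.iterrows():
        volume = imaging.load_volume(rec["volume_path"])
        roi = imaging.load_mask(
            rec["mask_path"],
            lesion_id=str(rec["lesion_id"]),
            patient_id=str(rec.get("patient_id", "")),
            district=str(rec.get("district", "liver")),
            timepoint=str(rec.get("timepoint", "T0")),
        )
        try:
            vec = feat.extract_all(volume, roi, hist_cfg, glcm_cfg)
        except ValueError as exc:
            logger.warning("lesion %s skipped: %s", rec["lesion_id"], exc)
            skipped.append({"lesion_id": rec["lesion_id"], "reason": str(exc)})
            continue
        rows[vec.lesion_id] = vec.values
    wide = pd.DataFrame.from_dict(rows, orient="index")
    wide.index.name = "lesion_id"
    return wide, pd.DataFrame(skipped, columns=["lesion_id", "reason"])


def load_feature_table(
    features_csv, labels_csv, label_column: str = "dichotomous", district_column: str = "district"
) -> selection.FeatureTable:
    """Assemble a FeatureTable from wide feature and label CSVs.

    Both files are indexed by ``lesion_id``; the label file provides the
    outcome column and optionally district and patient id.
    """
    features = pd.read_csv(features_csv, index_col="lesion_id")
    meta = pd.read_csv(labels_csv, index_col="lesion_id")
    common = features.index.intersection(meta.index)
    if common.empty:
        raise ValueError("no shared lesion ids between features and labels")
    features = features.loc[common]
    meta = meta.loc[common]
    district = meta[district_column] if district_column in meta else None
    patient = meta["patient_id"] if "patient_id" in meta else None
    numeric = features.select_dtypes(include=[np.number])
    complete = numeric.dropna(axis=1)
    dropped = sorted(set(numeric.columns) - set(complete.columns))
    if dropped:
        logger.warning("dropping %d feature(s) with missing values: %s", len(dropped), dropped)
    return selection.FeatureTable(
        features=complete, labels=meta[label_column], district=district, patient_id=patient
    )


def nested_cv_scores(
    table: selection.FeatureTable, cv: modeling.CVConfig, sort_mode="abs", p_value_mode="lrt"
) -> tuple[np.ndarray, list[tuple[str, ...]]]:
    """Leakage-free variant: feature selection is re-run inside each fold."""
    y = table.labels.to_numpy()
    groups = None if table.patient_id is None else table.patient_id.to_numpy()
    folds = modeling.kfold_split(y, cv, groups=groups)
    scores = np.full(len(y), np.nan)
    per_fold_features: list[tuple[str, ...]] = []
    for fold_id in range(cv.k):
        val = folds == fold_id
        train_table = table.subset(~val)
        sel = selection.forward_select(train_table, sort_mode=sort_mode, p_value_mode=p_value_mode)
        feats = sel.retained or (sel.ranking[0][0],)
        per_fold_features.append(tuple(feats))
        inner = modeling.CVConfig(
            k=cv.k, seed=cv.seed, stratified=cv.stratified, discriminant=cv.discriminant
        )
        clf = modeling._make_discriminant(inner.discriminant)
        Xtr = train_table.features[list(feats)].to_numpy(dtype=np.float64)
        clf.fit(Xtr, train_table.labels.to_numpy())
        class0 = int(np.flatnonzero(clf.classes_ == 0)[0])
        Xv = table.features.loc[val, list(feats)].to_numpy(dtype=np.float64)
        scores[val] = clf.predict_proba(Xv)[:, class0]
    return scores, per_fold_features


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, float_format=_FLOAT_FMT, index=index)


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the cohort-level pipeline and write the report bundle.

    Inputs are either simulated (``simulate.enabled``) or read from the
    configured feature/label CSVs. Any stage failure aborts with the
    stage name in the exception message.
    """
    out = Path(out_dir if out_dir is not None else config.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.config_hash(), "seed": config.cv.seed}

    # --- stage: inputs ---
    t1_features = None
    try:
        if config.simulate.enabled:
            spec = synth.CohortSpec(
                n_noise_features=config.simulate.n_noise_features,
                correlation=config.simulate.correlation,
                seed=config.cv.seed,
            )
            table, t1_features, _ = synth.sample_paired_cohort(spec)
        else:
            if not config.paths.features_csv or not config.paths.labels_csv:
                raise ValueError("features_csv and labels_csv are required unless simulating")
            table = load_feature_table(
                config.paths.features_csv,
                config.paths.labels_csv,
                config.label_column,
                config.district_column,
            )
            if config.paths.t1_features_csv:
                t1_features = pd.read_csv(config.paths.t1_features_csv, index_col="lesion_id")
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    # --- stage: selection ---
    try:
        sel = selection.forward_select(
            table,
            sort_mode=config.selection.sort_mode,
            p_value_mode=config.selection.p_value_mode,
        )
        with open(out / "selection.json", "w") as fh:
            json.dump({**provenance, **sel.to_dict()}, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"stage 'selection' failed: {exc}") from exc

    # --- stage: cross-validation + ROC ---
    try:
        cv = modeling.CVConfig(
            k=config.cv.k,
            seed=config.cv.seed,
            stratified=config.cv.stratified,
            group_by_patient=config.cv.group_by_patient,
            discriminant=config.cv.discriminant,
        )
        retained = sel.retained or (sel.ranking[0][0],)
        if config.cv.nested:
            scores, _ = nested_cv_scores(
                table, cv, config.selection.sort_mode, config.selection.p_value_mode
            )
        else:
            scores = modeling.cross_validated_scores(table, retained, cv)
        _write_csv(
            pd.DataFrame(
                {"score_nonresponse": scores, "label": table.labels.to_numpy()},
                index=table.features.index.rename("lesion_id"),
            ),
            out / "scores.csv",
        )
        roc = modeling.roc_curve(scores, table.labels.to_numpy(), positive_label=0)
        _write_csv(
            pd.DataFrame(
                {
                    "threshold": roc.thresholds,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                }
            ),
            out / "roc.csv",
            index=False,
        )
        summary = {
            **provenance,
            "retained_features": list(retained),
            "k": config.cv.k,
            "nested": config.cv.nested,
            "auc": roc.auc,
            "youden_cutoff": roc.youden_cutoff,
            "sensitivity_at_cutoff": roc.sens_at_cutoff,
            "specificity_at_cutoff": roc.spec_at_cutoff,
            "positive_class": "non_responder",
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluation' failed: {exc}") from exc

    # --- stage: delta + per-site + report ---
    try:
        delta_summaries: dict[str, pd.DataFrame] = {}
        if t1_features is not None:
            deltas = labeling.delta_table(table.features, t1_features)
            _write_csv(deltas, out / "deltas.csv")
            if table.district is not None:
                for district in sorted(table.district.unique()):
                    rows = table.district == district
                    if len(table.labels[rows].unique()) < 2:
                        continue
                    delta_summaries[district] = cohort.delta_group_summary(
                        deltas.loc[rows], table.labels[rows]
                    )
        per_site = []
        if table.district is not None:
            for district in sorted(table.district.unique()):
                rows = table.district == district
                if len(table.labels[rows].unique()) < 2 or rows.sum() < 4:
                    logger.warning("district %s skipped (single class or too small)", district)
                    continue
                per_site.append(cohort.per_site_analysis(table, district))
        report = cohort.build_report(
            table.labels,
            table.district if table.district is not None else pd.Series("all", index=table.features.index),
            per_site=per_site or None,
            delta_summaries=delta_summaries or None,
        )
        for name, df in report.items():
            _write_csv(df, out / f"report_{name}.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'report' failed: {exc}") from exc

    return {"out_dir": str(out), "summary": summary, "retained": list(retained)}
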