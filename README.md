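# petrad

A per-lesion PET radiomics response-prediction pipeline. Given 3-D SUV
volumes with binary lesion masks (NIfTI) — or synthetic surrogates — it:

1. enforces the ROI inclusion rule (>= 16 voxels) and discretizes lesion
   intensities with fixed absolute bounds (SUV 0–60, 64 bins);
2. extracts first-order histogram features (skewness, non-excess
   kurtosis, entropy, energy), conventional SUV statistics (SUVmin/mean/
   max/std, MTV, TLG), shape descriptors (volume, sphericity) and
   direction-averaged GLCM texture features;
3. labels each lesion PD/SD/PR/CR from paired baseline/follow-up size and
   SUVmax changes (±25% thresholds) and dichotomizes progression vs
   response;
4. ranks features by point-biserial correlation with the outcome and
   forward-selects them with a one-at-a-time logistic regression and a
   growing-p-value stopping rule;
5. evaluates a linear discriminant classifier with stratified k-fold
   cross-validation (k = 5 default), reporting the ROC curve, trapezoidal
   AUC and Youden-index cut-off (positive class = non-responder);
6. computes delta-radiomics (percent feature change between timepoints),
   per-district group comparisons (Mann–Whitney U) with single-feature
   ROCs, and deterministic report tables.

The `synth` module generates every input the pipeline needs: ellipsoidal
lesions with moment-matched intensity distributions, and per-district
feature cohorts calibrated to published responder/non-responder summary
statistics (embedded in `petrad.fixtures`).

## CLI

```sh
petrad simulate --mode paired --seed 3 --out sim/          # synthetic cohort
petrad extract  --metadata sim/metadata.csv --out feats.csv
petrad label    --measurements meas.csv --out labels.csv
petrad select   --features sim/features.csv --labels sim/labels.csv --out sel.json
petrad evaluate --features sim/features.csv --labels sim/labels.csv \
                --feature HISTO_Skewness --feature HISTO_Kurtosis --out-dir eval/
petrad delta    --t0 sim/features.csv --t1 sim/features_t1.csv --out deltas.csv
petrad per-site --features sim/features.csv --labels sim/labels.csv \
                --district liver --out-dir site/
petrad run      --config pipeline.yaml                      # full pipeline
```

`run` takes a YAML config validated against the schema in
`petrad.config` (discretization, GLCM, selection, CV, response-threshold
and path blocks); with `simulate.enabled: true` it runs end to end on a
calibrated surrogate cohort.

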