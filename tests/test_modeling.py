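import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from petrad.modeling import (
    CVConfig,
    cross_validated_scores,
    kfold_split,
    roc_curve,
    single_feature_roc,
    youden_cutoff,
)
from petrad.selection import FeatureTable


def make_table(x: np.ndarray, y, patient_id=None):
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(x.shape[1])])
    return FeatureTable(
        features=df,
        labels=pd.Series(y, index=df.index),
        patient_id=None if patient_id is None else pd.Series(patient_id, index=df.index),
    )


class TestKFoldSplit:
    def test_even_folds(self):
        y = np.array([0, 1] * 5)
        folds = kfold_split(y, CVConfig(k=5, seed=0))
        _, counts = np.unique(folds, return_counts=True)
        assert list(counts) == [2] * 5

    def test_stratification_within_one_row(self, rng):
        y = np.r_[np.zeros(60, int), np.ones(40, int)]
        folds = kfold_split(y, CVConfig(k=5, seed=3))
        for f in range(5):
            sub = y[folds == f]
            assert abs((sub == 0).sum() - 12) <= 1
            assert abs((sub == 1).sum() - 8) <= 1

    def test_same_seed_identical(self, rng):
        y = rng.integers(0, 2, 50)
        y[:4] = [0, 0, 1, 1]
        f1 = kfold_split(y, CVConfig(k=5, seed=9))
        f2 = kfold_split(y, CVConfig(k=5, seed=9))
        np.testing.assert_array_equal(f1, f2)
        f3 = kfold_split(y, CVConfig(k=5, seed=10))
        assert not np.array_equal(f1, f3)

    def test_folds_disjoint_exhaustive(self, rng):
        y = rng.integers(0, 2, 37)
        y[:4] = [0, 0, 1, 1]
        folds = kfold_split(y, CVConfig(k=5, seed=1))
        assert folds.min() >= 0 and folds.max() == 4
        assert len(folds) == 37

    def test_class_absent_from_training_raises(self):
        y = np.r_[np.zeros(9, int), np.ones(1, int)]
        with pytest.raises(ValueError):
            kfold_split(y, CVConfig(k=5, seed=0, stratified=False))

    def test_k_validation(self):
        with pytest.raises(ValueError):
            CVConfig(k=1)

    def test_group_splitting(self):
        y = np.array([0, 1] * 10)
        groups = np.repeat(np.arange(10), 2)
        folds = kfold_split(y, CVConfig(k=5, group_by_patient=True), groups=groups)
        for g in np.unique(groups):
            assert len(np.unique(folds[groups == g])) == 1


class TestCrossValidatedScores:
    def test_null_auc_near_half(self, rng):
        n = 400
        x = rng.normal(size=(n, 2))
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        scores = cross_validated_scores(make_table(x, y), ["f0", "f1"], CVConfig(k=5, seed=0))
        roc = roc_curve(scores, y, positive_label=0)
        assert roc.auc == pytest.approx(0.5, abs=0.1)

    def test_two_gaussian_closed_form_auc(self, rng):
        # N(0,1) vs N(2,1): AUC = Phi(2/sqrt(2)) ~ 0.921
        n = 500
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        x = rng.normal(size=n) + 2.0 * (y == 0)
        scores = cross_validated_scores(make_table(x[:, None], y), ["f0"], CVConfig(k=5, seed=2))
        roc = roc_curve(scores, y, positive_label=0)
        expected = sstats.norm.cdf(2 / np.sqrt(2))
        assert roc.auc == pytest.approx(expected, abs=0.03)

    def test_every_row_scored_once(self, rng):
        n = 53
        y = rng.integers(0, 2, n)
        y[:4] = [0, 0, 1, 1]
        x = rng.normal(size=(n, 3))
        scores = cross_validated_scores(make_table(x, y), ["f0", "f1", "f2"], CVConfig(k=5, seed=0))
        assert scores.shape == (n,)
        assert np.all(np.isfinite(scores))
        assert np.all((scores >= 0) & (scores <= 1))

    def test_missing_feature_raises(self, rng):
        table = make_table(rng.normal(size=(20, 1)), [0, 1] * 10)
        with pytest.raises(ValueError, match="absent"):
            cross_validated_scores(table, ["nope"], CVConfig(k=2))

    def test_collinear_features_still_scored(self, rng):
        # rank-deficient pooled covariance must not crash
        n = 60
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        base = rng.normal(size=n) + y
        x = np.c_[base, base, rng.normal(size=n)]
        scores = cross_validated_scores(
            make_table(x, y), ["f0", "f1", "f2"], CVConfig(k=5, seed=0)
        )
        assert np.all(np.isfinite(scores))

    def test_quadratic_variant(self, rng):
        n = 200
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        x = rng.normal(size=(n, 1)) * (1 + y[:, None])
        scores = cross_validated_scores(
            make_table(x, y), ["f0"], CVConfig(k=5, seed=0, discriminant="quadratic")
        )
        assert np.all(np.isfinite(scores))


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == 1.0
        assert roc.sens_at_cutoff == 1.0 and roc.spec_at_cutoff == 1.0
        assert roc.youden_j == pytest.approx(1.0)

    def test_constant_scores(self):
        roc = roc_curve([0.5] * 10, [0, 1] * 5)
        assert roc.auc == pytest.approx(0.5)

    def test_four_point_pair_counting_oracle(self):
        # concordant pairs out of 4: (0.35,0.1) yes, (0.35,0.4) no,
        # (0.8,0.1) yes, (0.8,0.4) yes -> AUC 0.75
        roc = roc_curve([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_auc_equals_pair_counting_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = rng.normal(size=n)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            pos, neg = scores[y == 1], scores[y == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = conc / (len(pos) * len(neg))
            assert roc_curve(scores, y).auc == pytest.approx(expected, abs=1e-12)

    def test_auc_equals_mann_whitney_u(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = rng.normal(size=n)  # continuous: tie-free a.s.
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            u = sstats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
            expected = u / ((y == 1).sum() * (y == 0).sum())
            assert roc_curve(scores, y).auc == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=80)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        a1 = roc_curve(scores, y).auc
        a2 = roc_curve(np.exp(scores), y).auc
        a3 = roc_curve(3 * scores - 7, y).auc
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert a1 == pytest.approx(a3, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])


class TestYouden:
    @staticmethod
    def exhaustive_scan(scores, y, positive_label=1):
        """Oracle: scan every candidate threshold for max J.

        Candidates are ranked by the exact integer numerator
        tp*n_neg - fp*n_pos (no float noise); ties prefer the lower
        threshold.
        """
        pos = np.asarray(y) == positive_label
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        best = (-np.inf, None, None, None)
        for t in np.unique(scores):
            pred = np.asarray(scores) >= t
            tp = int((pred & pos).sum())
            fp = int((pred & ~pos).sum())
            j_num = tp * n_neg - fp * n_pos
            if j_num > best[0]:  # ascending t: first max is lowest threshold
                best = (j_num, t, tp / n_pos, (n_neg - fp) / n_neg)
        j_num, t, sens, spec = best
        return sens + spec - 1, t, sens, spec

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 50))
            scores = np.round(rng.normal(size=n), 2)  # induce ties
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            roc = roc_curve(scores, y)
            j, t, sens, spec = self.exhaustive_scan(scores, y)
            assert roc.youden_cutoff == pytest.approx(t)
            assert roc.youden_j == pytest.approx(j, abs=1e-12)
            assert roc.sens_at_cutoff == pytest.approx(sens)
            assert roc.spec_at_cutoff == pytest.approx(spec)

    def test_youden_cutoff_function(self, rng):
        scores = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        roc = roc_curve(scores, y)
        cutoff, sens, spec = youden_cutoff(roc)
        assert cutoff == roc.youden_cutoff
        assert sens == roc.sens_at_cutoff and spec == roc.spec_at_cutoff


class TestSingleFeatureROC:
    def test_matches_lda_on_one_feature(self, rng):
        # the LDA posterior is monotone in a single feature, so the ROC and
        # AUC coincide with using the feature directly as score
        n = 120
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        x = rng.normal(size=n) + 1.2 * (y == 0)
        feat_auc = single_feature_roc(x, y, positive_label=0).auc
        clf = LinearDiscriminantAnalysis().fit(x[:, None], y)
        post0 = clf.predict_proba(x[:, None])[:, list(clf.classes_).index(0)]
        lda_auc = roc_curve(post0, y, positive_label=0).auc
        assert feat_auc == pytest.approx(lda_auc, abs=1e-12)

    def test_auto_orientation(self, rng):
        n = 100
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        x = rng.normal(size=n) - 2.0 * (y == 0)  # lower in positives
        roc = single_feature_roc(x, y, positive_label=0, orient="auto")
        assert roc.auc > 0.5
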