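import math

import numpy as np
import pytest

from petrad import synth
from petrad.features import (
    GLCMConfig,
    conventional_features,
    extract_all,
    glcm_features,
    glcm_matrices,
    histo_features,
    shape_features,
)
from petrad.imaging import DiscretizationConfig, discretize

from conftest import make_roi, make_volume


def brute_force_histo_moments(values, cfg):
    """Independent oracle: moments computed from per-voxel discretized bin
    centers with plain python sums."""
    w = cfg.resolved_bin_width
    centers = [
        cfg.lower + (min(int((v - cfg.lower) // w), cfg.n_bins - 1) if v >= cfg.lower else 0) * w
        + w / 2.0
        for v in values
    ]
    n = len(centers)
    mu = sum(centers) / n
    var = sum((c - mu) ** 2 for c in centers) / n
    sd = math.sqrt(var)
    skew = sum((c - mu) ** 3 for c in centers) / n / sd**3
    kurt = sum((c - mu) ** 4 for c in centers) / n / var**2
    return skew, kurt


class TestHistoFeatures:
    def test_symmetric_two_bin(self, default_cfg):
        # equal mass in two bins: skewness 0, (non-excess) kurtosis 1
        vals = [10.0] * 50 + [20.0] * 50
        out = histo_features(discretize(vals, default_cfg))
        assert out["HISTO_Skewness"] == pytest.approx(0.0, abs=1e-12)
        assert out["HISTO_Kurtosis"] == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_limit(self, default_cfg):
        rng = np.random.default_rng(0)
        vals = rng.normal(30.0, 5.0, size=100_000)
        out = histo_features(discretize(vals, default_cfg))
        assert out["HISTO_Kurtosis"] == pytest.approx(3.0, abs=0.1)
        assert out["HISTO_Skewness"] == pytest.approx(0.0, abs=0.05)

    def test_matches_brute_force_oracle(self, rng, default_cfg):
        for _ in range(100):
            vals = rng.uniform(0, 59, size=rng.integers(16, 200))
            out = histo_features(discretize(vals, default_cfg))
            skew, kurt = brute_force_histo_moments(vals, default_cfg)
            assert out["HISTO_Skewness"] == pytest.approx(skew, abs=1e-9)
            assert out["HISTO_Kurtosis"] == pytest.approx(kurt, abs=1e-9)

    def test_moment_inequality(self, rng, default_cfg):
        # kurtosis >= skewness^2 + 1 for every distribution
        for _ in range(200):
            vals = rng.lognormal(2.0, rng.uniform(0.1, 1.0), size=rng.integers(16, 100))
            out = histo_features(discretize(vals, default_cfg))
            if math.isnan(out["HISTO_Skewness"]):
                continue
            assert out["HISTO_Kurtosis"] >= out["HISTO_Skewness"] ** 2 + 1 - 1e-9

    def test_degenerate_flagged_missing(self, default_cfg):
        out = histo_features(discretize(np.full(20, 30.0), default_cfg))
        assert math.isnan(out["HISTO_Skewness"])
        assert math.isnan(out["HISTO_Kurtosis"])
        assert out["HISTO_Entropy"] == 0.0
        assert out["HISTO_Energy"] == 1.0

    def test_entropy_energy_ranges(self, rng, default_cfg):
        vals = rng.uniform(0, 59, 500)
        out = histo_features(discretize(vals, default_cfg))
        assert 0 < out["HISTO_Energy"] <= 1
        assert out["HISTO_Entropy"] >= 0
        assert out["HISTO_Entropy_log10"] == pytest.approx(
            out["HISTO_Entropy"] * math.log10(2), rel=1e-12
        )


class TestConventionalFeatures:
    def test_order_statistics(self):
        out = conventional_features([1.0, 5.0, 3.0], (1, 1, 1))
        assert out["SUV_max"] == 5 and out["SUV_min"] == 1 and out["SUV_mean"] == 3

    def test_mtv_16_voxels(self):
        side = 27.6875 ** (1 / 3)
        out = conventional_features(np.ones(16), (side, side, side))
        assert out["MTV"] == pytest.approx(0.443, abs=1e-9)

    def test_constant_roi(self):
        out = conventional_features(np.full(16, 4.0), (3, 3, 3))
        assert out["SUV_std"] == 0.0
        assert out["TLG"] == pytest.approx(4.0 * out["MTV"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            conventional_features([], (1, 1, 1))


class TestShapeFeatures:
    def test_single_voxel_cube(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        out = shape_features(make_roi(mask), (1.0, 1.0, 1.0))
        assert out["SHAPE_Volume_mL"] == pytest.approx(0.001)
        # cube: A = 6, sphericity = pi^(1/3) * 6^(2/3) / 6
        assert out["SHAPE_Sphericity"] == pytest.approx(
            math.pi ** (1 / 3) * 6 ** (2 / 3) / 6, rel=1e-12
        )

    @staticmethod
    def _ball_mask(radius, shape):
        c = (np.asarray(shape) - 1) / 2
        idx = np.indices(shape)
        r2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
        return r2 <= radius**2

    def test_refinement_increases_sphericity(self):
        coarse = shape_features(make_roi(self._ball_mask(4, (11, 11, 11))), (2, 2, 2))
        fine = shape_features(make_roi(self._ball_mask(8, (21, 21, 21))), (1, 1, 1))
        assert fine["SHAPE_Sphericity"] > coarse["SHAPE_Sphericity"]
        assert fine["SHAPE_Sphericity"] < 1.0

    def test_volume_equals_mtv(self, random_volume_roi):
        vol, roi = random_volume_roi
        shp = shape_features(roi, vol.spacing)
        conv = conventional_features(vol.voxels[roi.mask], vol.spacing)
        assert shp["SHAPE_Volume_mL"] == pytest.approx(conv["MTV"], rel=1e-12)

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            shape_features(make_roi(np.zeros((2, 2, 2))), (1, 1, 1))


class TestGLCM:
    def test_constant_roi(self, default_cfg):
        vol = make_volume(np.full((4, 4, 4), 10.0))
        roi = make_roi(np.ones((4, 4, 4)))
        out = glcm_features(vol, roi, default_cfg)
        assert out["GLCM_Energy"] == pytest.approx(1.0)
        assert out["GLCM_Entropy"] == pytest.approx(0.0)
        assert out["GLCM_Contrast"] == pytest.approx(0.0)
        assert out["GLCM_Homogeneity"] == pytest.approx(1.0)

    def test_alternating_stripe_hand_enumeration(self, default_cfg):
        # 1-D stripe a,b,a,b..., distance 1, single direction: all co-occurrence
        # mass on (a,b) and (b,a) -> Energy 0.5, Contrast (a-b)^2 in level units
        a_val, b_val = 10.0, 20.0  # levels 10 and 21 (width 0.9375)
        n = 12
        grid = np.zeros((n, 1, 1))
        grid[::2, 0, 0] = a_val
        grid[1::2, 0, 0] = b_val
        vol = make_volume(grid)
        roi = make_roi(np.ones((n, 1, 1)))
        cfg = GLCMConfig(directions=((1, 0, 0),))
        out = glcm_features(vol, roi, default_cfg, cfg)
        la = int(a_val / 0.9375)
        lb = int(b_val / 0.9375)
        assert out["GLCM_Energy"] == pytest.approx(0.5)
        assert out["GLCM_Contrast"] == pytest.approx((la - lb) ** 2)
        assert out["GLCM_Entropy"] == pytest.approx(1.0)
        assert out["GLCM_Dissimilarity"] == pytest.approx(abs(la - lb))

    def test_matrices_normalized_per_direction(self, random_volume_roi, default_cfg):
        vol, roi = random_volume_roi
        mats = glcm_matrices(vol, roi, default_cfg, GLCMConfig())
        assert len(mats) == 13
        for mat in mats.values():
            assert mat.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(mat, mat.T)

    def test_energy_entropy_bounds(self, random_volume_roi, default_cfg):
        vol, roi = random_volume_roi
        out = glcm_features(vol, roi, default_cfg)
        assert 0 < out["GLCM_Energy"] <= 1
        assert out["GLCM_Entropy"] >= 0

    def test_no_pairs_flagged_missing(self, default_cfg):
        # two isolated voxels further than distance 1 apart in every direction
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = mask[4, 4, 4] = True
        vol = make_volume(np.ones((5, 5, 5)))
        out = glcm_features(vol, make_roi(mask), default_cfg)
        assert all(math.isnan(v) for v in out.values())

    def test_2d_mode(self, random_volume_roi, default_cfg):
        vol, roi = random_volume_roi
        mats = glcm_matrices(vol, roi, default_cfg, GLCMConfig(directions="2D-4dir"))
        assert len(mats) == 4


class TestExtractAll:
    def test_constant_lesion_degeneracy_flags(self):
        vol = make_volume(np.full((4, 4, 4), 7.0))
        roi = make_roi(np.ones((4, 4, 4)))
        vec = extract_all(vol, roi)
        assert math.isnan(vec["HISTO_Skewness"])
        assert math.isnan(vec["RAW_Skewness"])
        assert vec["SUV_mean"] == 7.0
        assert vec["SUV_std"] == 0.0

    def test_determinism(self, random_volume_roi):
        vol, roi = random_volume_roi
        v1 = extract_all(vol, roi)
        v2 = extract_all(vol, roi)
        assert v1.values == v2.values

    def test_right_skewed_lesion(self):
        vol, roi = synth.synth_lesion_volume(
            synth.LesionSpec(n_voxels=1500, skewness=2.0), seed=11
        )
        vec = extract_all(vol, roi)
        assert vec["HISTO_Skewness"] > 0.5

    def test_small_roi_rejected(self):
        vol = make_volume(np.ones((3, 3, 3)))
        mask = np.zeros((3, 3, 3), bool)
        mask.flat[:10] = True
        with pytest.raises(ValueError, match="rejected"):
            extract_all(vol, make_roi(mask))

    def test_bin_preserving_shift_leaves_discretized_features(self, rng, default_cfg):
        # shifting by an exact multiple of the bin width changes only location
        base = rng.uniform(5, 25, size=(6, 6, 6))
        shift = 2 * default_cfg.resolved_bin_width
        roi = make_roi(np.ones((6, 6, 6)))
        v1 = extract_all(make_volume(base), roi)
        v2 = extract_all(make_volume(base + shift), roi)
        for name in (
            "HISTO_Skewness",
            "HISTO_Kurtosis",
            "HISTO_Entropy",
            "HISTO_Energy",
            "GLCM_Energy",
            "GLCM_Entropy",
            "GLCM_Contrast",
        ):
            assert v1[name] == pytest.approx(v2[name], abs=1e-9), name
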