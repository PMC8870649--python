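"""Per-ROI radiomics features: histogram moments, conventional SUV statistics,
shape descriptors and grey-level co-occurrence (GLCM) texture.

Histogram features are computed on discretized bin centers; raw-value
variants are emitted under ``RAW_`` names for diagnostics. Degenerate
statistics (zero spread, no voxel pairs) are reported as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .imaging import (
    DiscretizationConfig,
    IntensityHistogram,
    LesionROI,
    PETVolume,
    discretize,
    roi_voxels,
    validate_roi,
)

__all__ = [
    "GLCMConfig",
    "FeatureVector",
    "histo_features",
    "conventional_features",
    "shape_features",
    "glcm_matrices",
    "glcm_features",
    "extract_all",
]

# 13 unique 3-D direction offsets (half of the 26-neighbourhood).
_OFFSETS_3D = tuple(
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) > (0, 0, 0)
)
# 4 in-plane directions (axes 0/1), applied slice-wise along axis 2.
_OFFSETS_2D = ((1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0))


@dataclass(frozen=True)
class GLCMConfig:
    """Co-occurrence matrix configuration.

    ``directions`` is ``"3D-13dir"`` (default), ``"2D-4dir"`` or an explicit
    tuple of integer offsets. Matrices are symmetric, normalized per
    direction, and features are averaged over directions with voxel pairs.
    """

    distance: int = 1
    directions: str | tuple = "3D-13dir"

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")

    def offsets(self) -> tuple[tuple[int, int, int], ...]:
        if self.directions == "3D-13dir":
            base = _OFFSETS_3D
        elif self.directions == "2D-4dir":
            base = _OFFSETS_2D
        else:
            base = tuple(tuple(int(x) for x in off) for off in self.directions)
        return tuple(tuple(self.distance * c for c in off) for off in base)


@dataclass
class FeatureVector:
    """Named feature values for one lesion."""

    lesion_id: str
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def histo_features(hist: IntensityHistogram) -> dict[str, float]:
    """First-order statistics of the discretized intensity histogram.

    Over bin centers ``x_i`` with probabilities ``p_i``: skewness is the
    third and kurtosis the fourth (non-excess, normal -> 3) standardized
    moment; entropy is Shannon entropy (log2, with a log10 variant);
    energy is the sum of squared probabilities.
    """
    p = hist.probabilities
    x = hist.bin_centers
    mu = float(np.sum(p * x))
    var = float(np.sum(p * (x - mu) ** 2))
    nz = p[p > 0]
    entropy2 = float(-np.sum(nz * np.log2(nz)))
    out = {
        "HISTO_Entropy": entropy2,
        "HISTO_Entropy_log10": float(-np.sum(nz * np.log10(nz))),
        "HISTO_Energy": float(np.sum(p**2)),
    }
    if var <= 0:
        out["HISTO_Skewness"] = math.nan
        out["HISTO_Kurtosis"] = math.nan
    else:
        sd = math.sqrt(var)
        out["HISTO_Skewness"] = float(np.sum(p * (x - mu) ** 3) / sd**3)
        out["HISTO_Kurtosis"] = float(np.sum(p * (x - mu) ** 4) / var**2)
    return out


def conventional_features(values, spacing) -> dict[str, float]:
    """Order statistics and volume-weighted uptake of the raw SUV values.

    MTV is the segmented volume in mL; TLG is ``SUV_mean * MTV``.
    Standard deviation is the population (ddof=0) value.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty SUV value list")
    dx, dy, dz = spacing
    mtv_ml = values.size * dx * dy * dz / 1000.0
    mean = float(values.mean())
    return {
        "SUV_min": float(values.min()),
        "SUV_mean": mean,
        "SUV_max": float(values.max()),
        "SUV_std": float(values.std(ddof=0)),
        "MTV": mtv_ml,
        "TLG": mean * mtv_ml,
    }


def shape_features(roi: LesionROI, spacing) -> dict[str, float]:
    """Voxelized volume (mL) and sphericity.

    Surface area is obtained by face counting on the binary mask with
    anisotropic face areas; sphericity is
    ``pi**(1/3) * (6V)**(2/3) / A`` (1 for a perfect ball).
    """
    mask = roi.mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    dx, dy, dz = (float(s) for s in spacing)
    volume_mm3 = n * dx * dy * dz

    face_areas = (dy * dz, dx * dz, dx * dy)
    area = 0.0
    for axis, a in enumerate(face_areas):
        padded = np.pad(mask, [(1, 1) if ax == axis else (0, 0) for ax in range(3)])
        exposed = np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum()
        area += a * float(exposed)

    sphericity = math.pi ** (1.0 / 3.0) * (6.0 * volume_mm3) ** (2.0 / 3.0) / area
    return {"SHAPE_Volume_mL": volume_mm3 / 1000.0, "SHAPE_Sphericity": sphericity}


def glcm_matrices(
    volume: PETVolume,
    roi: LesionROI,
    hist_cfg: DiscretizationConfig = DiscretizationConfig(),
    glcm_cfg: GLCMConfig = GLCMConfig(),
) -> dict[tuple[int, int, int], np.ndarray]:
    """Symmetric, per-direction-normalized co-occurrence matrices.

    Only pairs with both voxels inside the mask contribute. Directions with
    no valid pair are omitted from the result.
    """
    mask = roi.mask
    if mask.shape != volume.voxels.shape:
        raise ValueError("mask shape does not match volume shape")
    w = hist_cfg.resolved_bin_width
    levels = np.clip(
        np.floor((volume.voxels - hist_cfg.lower) / w).astype(np.int64), 0, hist_cfg.n_bins - 1
    )
    n_levels = hist_cfg.n_bins
    out: dict[tuple[int, int, int], np.ndarray] = {}
    for off in glcm_cfg.offsets():
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, o in enumerate(off):
            if o > 0:
                src[ax], dst[ax] = slice(None, -o), slice(o, None)
            elif o < 0:
                src[ax], dst[ax] = slice(-o, None), slice(None, o)
        src_t, dst_t = tuple(src), tuple(dst)
        valid = mask[src_t] & mask[dst_t]
        if not valid.any():
            continue
        i = levels[src_t][valid]
        j = levels[dst_t][valid]
        mat = np.bincount(i * n_levels + j, minlength=n_levels * n_levels).astype(np.float64)
        mat = mat.reshape(n_levels, n_levels)
        mat = mat + mat.T  # symmetric pairs
        out[off] = mat / mat.sum()
    return out


_GLCM_NAMES = (
    "GLCM_Energy",
    "GLCM_Entropy",
    "GLCM_Homogeneity",
    "GLCM_Contrast",
    "GLCM_Correlation",
    "GLCM_Dissimilarity",
)


def _glcm_single(mat: np.ndarray) -> dict[str, float]:
    n = mat.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    p = mat
    nz = p[p > 0]
    diff = i - j
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    if var_i > 0 and var_j > 0:
        corr = float(np.sum((i - mu_i) * (j - mu_j) * p) / math.sqrt(var_i * var_j))
    else:
        corr = math.nan
    return {
        "GLCM_Energy": float(np.sum(p**2)),
        "GLCM_Entropy": float(-np.sum(nz * np.log2(nz))),
        "GLCM_Homogeneity": float(np.sum(p / (1.0 + np.abs(diff)))),
        "GLCM_Contrast": float(np.sum(diff**2 * p)),
        "GLCM_Correlation": corr,
        "GLCM_Dissimilarity": float(np.sum(np.abs(diff) * p)),
    }


def glcm_features(
    volume: PETVolume,
    roi: LesionROI,
    hist_cfg: DiscretizationConfig = DiscretizationConfig(),
    glcm_cfg: GLCMConfig = GLCMConfig(),
) -> dict[str, float]:
    """Direction-averaged GLCM texture features.

    Returns NaN for every feature when no direction has a valid voxel pair.
    """
    mats = glcm_matrices(volume, roi, hist_cfg, glcm_cfg)
    if not mats:
        return {name: math.nan for name in _GLCM_NAMES}
    per_dir = [_glcm_single(m) for m in mats.values()]
    out: dict[str, float] = {}
    for name in _GLCM_NAMES:
        vals = np.array([d[name] for d in per_dir])
        out[name] = float(np.nanmean(vals)) if np.isfinite(vals).any() else math.nan
    return out


def extract_all(
    volume: PETVolume,
    roi: LesionROI,
    hist_cfg: DiscretizationConfig = DiscretizationConfig(),
    glcm_cfg: GLCMConfig = GLCMConfig(),
    min_voxels: int = 16,
) -> FeatureVector:
    """Extract the full named feature vector for one ROI.

    Raises ``ValueError`` when the ROI fails the inclusion rule; callers
    batching many lesions should catch and log the reason.
    """
    check = validate_roi(roi, volume, min_voxels=min_voxels)
    if not check.passed:
        raise ValueError(f"ROI {roi.lesion_id!r} rejected: {check.reason}")
    values = roi_voxels(volume, roi)
    hist = discretize(values, hist_cfg)
    out: dict[str, float] = {}
    out.update(histo_features(hist))
    out.update(conventional_features(values, volume.spacing))
    out.update(shape_features(roi, volume.spacing))
    out.update(glcm_features(volume, roi, hist_cfg, glcm_cfg))
    # raw (undiscretized) moment diagnostics
    if values.std(ddof=0) > 0:
        out["RAW_Skewness"] = float(sstats.skew(values, bias=True))
        out["RAW_Kurtosis"] = float(sstats.kurtosis(values, fisher=False, bias=True))
    else:
        out["RAW_Skewness"] = math.nan
        out["RAW_Kurtosis"] = math.nan
    return FeatureVector(lesion_id=roi.lesion_id, values=out)
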