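"""PET volumes, lesion ROIs and fixed-bound intensity discretization.

Volumes are 3-D grids of SUV (standardized uptake value, dimensionless)
with millimetre voxel spacing. Lesion ROIs are binary masks defined on the
same grid. Intensities are discretized with a fixed absolute bound
configuration (default SUV 0-60 over 64 bins) prior to histogram and
texture computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "DISTRICTS",
    "TIMEPOINTS",
    "FormatError",
    "PETVolume",
    "LesionROI",
    "DiscretizationConfig",
    "IntensityHistogram",
    "ROIValidation",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "roi_voxels",
    "validate_roi",
    "discretize",
]

DISTRICTS = ("liver", "lymph_node", "bone", "parenchymal_other")
TIMEPOINTS = ("T0", "T1")

#: minimum ROI size in voxels for textural feature computation
MIN_ROI_VOXELS = 16


class FormatError(ValueError):
    """Raised when an input image or mask violates the expected format."""


@dataclass
class PETVolume:
    """A 3-D SUV image with voxel spacing in mm.

    Parameters
    ----------
    voxels : ndarray
        3-D array of SUV values; must be finite and non-negative.
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in millimetres, all > 0.
    origin : tuple of float
        Physical offset of the first voxel in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise FormatError(f"volume must be 3-D, got {self.voxels.ndim}-D")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("volume contains non-finite SUV values")
        if np.any(self.voxels < 0):
            raise FormatError("volume contains negative SUV values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be three positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class LesionROI:
    """Binary lesion mask congruent with one :class:`PETVolume`."""

    mask: np.ndarray
    lesion_id: str
    patient_id: str = ""
    district: str = "liver"
    timepoint: str = "T0"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise FormatError(f"mask must be 3-D, got {self.mask.ndim}-D")
        if self.district not in DISTRICTS:
            raise ValueError(f"district {self.district!r} not in {DISTRICTS}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint {self.timepoint!r} not in {TIMEPOINTS}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class DiscretizationConfig:
    """Fixed absolute-bound discretization of SUV intensities.

    By default the bin width is ``(upper - lower) / n_bins``; an explicit
    ``bin_width`` may be given instead (values beyond the implied top edge
    are absorbed by the last bin).
    """

    lower: float = 0.0
    upper: float = 60.0
    n_bins: int = 64
    bin_width: float | None = None

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.bin_width is not None and self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def resolved_bin_width(self) -> float:
        if self.bin_width is not None:
            return float(self.bin_width)
        return (self.upper - self.lower) / self.n_bins

    @property
    def bin_edges(self) -> np.ndarray:
        w = self.resolved_bin_width
        return self.lower + w * np.arange(self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        w = self.resolved_bin_width
        return self.lower + w * (np.arange(self.n_bins) + 0.5)


@dataclass
class IntensityHistogram:
    """Per-bin voxel counts and normalized frequencies of one ROI."""

    counts: np.ndarray
    probabilities: np.ndarray
    bin_edges: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ROIValidation:
    """Result of the ROI inclusion rule check."""

    passed: bool
    reason: str
    n_voxels: int
    volume_mm3: float

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    def __bool__(self) -> bool:
        return self.passed


def load_volume(path) -> PETVolume:
    """Load a 3-D NIfTI SUV image.

    Spacing is taken from the header zooms, the origin from the affine
    translation; voxel values are returned unchanged.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several incompatible types
        raise FormatError(f"cannot read NIfTI image {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D image, got {data.ndim}-D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return PETVolume(voxels=data, spacing=zooms, origin=origin)


def load_mask(path, **roi_kwargs) -> LesionROI:
    """Load a binary lesion mask from NIfTI; nonzero voxels are in-mask."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI mask {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D mask, got {data.ndim}-D")
    roi_kwargs.setdefault("lesion_id", str(path))
    return LesionROI(mask=data != 0, **roi_kwargs)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: PETVolume, path) -> None:
    nib.save(nib.Nifti1Image(volume.voxels, _affine(volume.spacing, volume.origin)), str(path))


def save_mask(roi: LesionROI, volume: PETVolume, path) -> None:
    nib.save(
        nib.Nifti1Image(roi.mask.astype(np.uint8), _affine(volume.spacing, volume.origin)),
        str(path),
    )


def _check_congruent(volume: PETVolume, roi: LesionROI) -> None:
    if roi.mask.shape != volume.voxels.shape:
        raise ValueError(
            f"mask shape {roi.mask.shape} does not match volume shape {volume.voxels.shape}"
        )


def roi_voxels(volume: PETVolume, roi: LesionROI) -> np.ndarray:
    """SUV values at mask-true voxels in lexicographic (C-order) index order."""
    _check_congruent(volume, roi)
    if not roi.mask.any():
        raise ValueError(f"ROI {roi.lesion_id!r} is empty")
    return volume.voxels[roi.mask]


def validate_roi(
    roi: LesionROI, volume: PETVolume, min_voxels: int = MIN_ROI_VOXELS
) -> ROIValidation:
    """Apply the minimum-size inclusion rule (default 16 voxels).

    The physical ROI volume (voxel count x voxel volume) is reported
    alongside the verdict.
    """
    _check_congruent(volume, roi)
    n = roi.n_voxels
    vol_mm3 = n * volume.voxel_volume_mm3
    if n == 0:
        return ROIValidation(False, "empty ROI", 0, 0.0)
    if n < min_voxels:
        return ROIValidation(False, f"ROI has {n} voxels, fewer than {min_voxels}", n, vol_mm3)
    return ROIValidation(True, "ok", n, vol_mm3)


def discretize(values, cfg: DiscretizationConfig = DiscretizationConfig()) -> IntensityHistogram:
    """Bin SUV values into a fixed-bound intensity histogram.

    Bin index is ``floor((v - lower) / bin_width)``; values below the lower
    bound map to bin 0 and values at or above the top edge to the last bin,
    making the operation total on ``[0, inf)``.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot discretize an empty value list")
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain NaN or infinity")
    w = cfg.resolved_bin_width
    idx = np.floor((values - cfg.lower) / w).astype(np.int64)
    idx = np.clip(idx, 0, cfg.n_bins - 1)
    counts = np.bincount(idx, minlength=cfg.n_bins).astype(np.int64)
    return IntensityHistogram(
        counts=counts,
        probabilities=counts / counts.sum(),
        bin_edges=cfg.bin_edges,
    )
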