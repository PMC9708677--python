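"""Mirror-ROI CT densitometry: percent net water uptake (NWU).

Ischemic brain tissue takes up water as cytotoxic and vasogenic edema
develop, lowering its x-ray attenuation.  The percent net water uptake of
an ischemic lesion on non-contrast CT is estimated by comparing the mean
Hounsfield-unit (HU) density of the lesion ROI, ``D_ischemic``, with the
mean density of the same ROI mirrored onto the contralateral, unaffected
hemisphere, ``D_normal``::

    %NWU = (1 - D_ischemic / D_normal) * 100

Voxels outside the 20-80 HU window are discarded from both ROIs before
averaging, which removes cerebrospinal fluid (low HU) and calcifications
(high HU) that would otherwise bias the densitometric means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "ROISet",
    "DensityPair",
    "NWUResult",
    "mirror_roi",
    "filter_hu",
    "compute_nwu",
]

HU_WINDOW_DEFAULT = (20.0, 80.0)


@dataclass(frozen=True)
class CTVolume:
    """A 3-D scalar CT grid in Hounsfield units with geometry.

    Parameters
    ----------
    voxels : ndarray
        3-D array of HU values.
    spacing_mm : tuple of float
        Per-axis voxel size in millimetres; strictly positive.
    midsagittal_axis : int
        Grid axis orthogonal to the midsagittal (left-right symmetry) plane.
    midsagittal_index : float
        Position of the symmetry plane along that axis, in voxel index
        units.  May be half-integer for even-sized grids (plane between
        two voxel columns).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    midsagittal_axis: int = 0
    midsagittal_index: float | None = None

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("voxels must be a non-empty 3-D grid")
        object.__setattr__(self, "voxels", v)
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing_mm must be three strictly positive values")
        object.__setattr__(self, "spacing_mm", sp)
        if not 0 <= self.midsagittal_axis <= 2:
            raise ValueError("midsagittal_axis must be 0, 1 or 2")
        if self.midsagittal_index is None:
            object.__setattr__(
                self, "midsagittal_index", (v.shape[self.midsagittal_axis] - 1) / 2.0
            )
        mi = float(self.midsagittal_index)
        if not 0 <= mi <= v.shape[self.midsagittal_axis] - 1:
            raise ValueError("midsagittal_index outside grid bounds")
        object.__setattr__(self, "midsagittal_index", mi)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @classmethod
    def from_nifti(cls, path: str | Path, midsagittal_axis: int = 0,
                   midsagittal_index: float | None = None) -> "CTVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        data = np.asanyarray(img.dataobj).astype(np.float64)
        return cls(data, spacing, midsagittal_axis, midsagittal_index)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine), str(path))


def mirror_roi(mask: np.ndarray, axis: int = 0, plane_index: float | None = None) -> np.ndarray:
    """Reflect a binary ROI mask across the midsagittal plane.

    The output mask is the voxel-wise reflection of ``mask`` across the
    plane at ``plane_index`` along ``axis`` (default: grid centre), the
    deterministic analog of manually mirroring a lesion ROI onto the
    contralateral hemisphere.

    Raises
    ------
    ValueError
        If the mask is empty, the reflection would leave the grid, or the
        reflection intersects the original mask (a lesion touching or
        crossing the midline has no uncontaminated contralateral mirror).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    if plane_index is None:
        plane_index = (mask.shape[axis] - 1) / 2.0
    idx = np.argwhere(mask)
    reflected = idx.copy()
    reflected[:, axis] = np.round(2.0 * plane_index - idx[:, axis]).astype(np.intp)
    if reflected[:, axis].min() < 0 or reflected[:, axis].max() >= mask.shape[axis]:
        raise ValueError("reflected ROI falls outside the grid")
    out = np.zeros_like(mask)
    out[tuple(reflected.T)] = True
    if (out & mask).any():
        raise ValueError(
            "ROI intersects its own reflection: lesion crosses the midsagittal plane"
        )
    return out


def filter_hu(values: np.ndarray, lo: float = HU_WINDOW_DEFAULT[0],
              hi: float = HU_WINDOW_DEFAULT[1]) -> np.ndarray:
    """Keep HU samples inside the inclusive [lo, hi] window, order preserved.

    The default 20-80 HU window excludes CSF and calcification voxels from
    densitometric ROI means.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("HU samples must be finite")
    return values[(values >= lo) & (values <= hi)]


@dataclass(frozen=True)
class DensityPair:
    """Filtered mean densities of the ischemic ROI and its mirror."""

    d_ischemic: float
    d_normal: float
    n_ischemic: int
    n_normal: int


@dataclass(frozen=True)
class NWUResult:
    """Percent net water uptake with densitometric provenance."""

    nwu_pct: float
    density_pair: DensityPair

    def to_dict(self) -> dict:
        dp = self.density_pair
        return {
            "nwu_pct": self.nwu_pct,
            "d_ischemic": dp.d_ischemic,
            "d_normal": dp.d_normal,
            "n_ischemic": dp.n_ischemic,
            "n_normal": dp.n_normal,
        }


@dataclass(frozen=True)
class ROISet:
    """Ischemic lesion mask paired with its contralateral mirror mask."""

    ischemic_mask: np.ndarray
    mirror_mask: np.ndarray

    def __post_init__(self):
        im = np.asarray(self.ischemic_mask).astype(bool)
        mm = np.asarray(self.mirror_mask).astype(bool)
        if im.shape != mm.shape:
            raise ValueError("ischemic and mirror masks must share a shape")
        if (im & mm).any():
            raise ValueError("ischemic and mirror masks must be disjoint")
        object.__setattr__(self, "ischemic_mask", im)
        object.__setattr__(self, "mirror_mask", mm)

    @classmethod
    def from_lesion(cls, ischemic_mask: np.ndarray, axis: int = 0,
                    plane_index: float | None = None) -> "ROISet":
        """Build the ROI pair by mirroring the lesion across the midline."""
        return cls(ischemic_mask, mirror_roi(ischemic_mask, axis, plane_index))


def _roi_density(ct: CTVolume, mask: np.ndarray, lo: float, hi: float,
                 statistic: str, label: str) -> tuple[float, int]:
    samples = ct.voxels[np.asarray(mask, dtype=bool)]
    kept = filter_hu(samples, lo, hi)
    if kept.size == 0:
        raise ValueError(
            f"no {label} ROI voxels survive the [{lo}, {hi}] HU filter"
        )
    stat = np.median if statistic == "median" else np.mean
    return float(stat(kept)), int(kept.size)


def compute_nwu(ct: CTVolume, rois: ROISet, hu_lo: float = HU_WINDOW_DEFAULT[0],
                hu_hi: float = HU_WINDOW_DEFAULT[1], statistic: str = "mean") -> NWUResult:
    """Percent net water uptake of a lesion via mirror-ROI densitometry.

    Computes filtered ROI densities ``D_ischemic`` and ``D_normal`` and
    returns ``(1 - D_ischemic / D_normal) * 100``.  Negative values (lesion
    denser than mirror, possible under noise) are returned as computed,
    not clipped, so that recovery statistics stay unbiased.

    Parameters
    ----------
    statistic : {"mean", "median"}
        ROI density summary; volumetric mean is the default.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if rois.ischemic_mask.shape != ct.shape:
        raise ValueError("ROI masks do not match the CT grid shape")
    d_isch, n_isch = _roi_density(ct, rois.ischemic_mask, hu_lo, hu_hi, statistic, "ischemic")
    d_norm, n_norm = _roi_density(ct, rois.mirror_mask, hu_lo, hu_hi, statistic, "mirror")
    assert d_norm > 0, "filtered contralateral density cannot be zero (HU floor > 0)"
    nwu = (1.0 - d_isch / d_norm) * 100.0
    return NWUResult(float(nwu), DensityPair(d_isch, d_norm, n_isch, n_norm))
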