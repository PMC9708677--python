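"""Synthetic head-CT / CT-perfusion phantoms with known ground truth.

The phantom is a deliberately simple "brain": an ellipsoid of uniform
parenchymal density in an axial grid, with the midsagittal plane at the
central sagittal slice, symmetric CSF ventricles, and an ellipsoidal
ischemic lesion confined to one hemisphere.  The lesion density encodes a
known true net water uptake through the generative inverse of the
densitometric formula::

    lesion_HU = tissue_HU * (1 - true_nwu_pct / 100)

so that mirror-ROI densitometry on the noise-free phantom recovers
``true_nwu_pct`` exactly.  Small CSF and calcification inclusions are
embedded inside the lesion ROI to exercise the 20-80 HU filter, and
concentric sub-regions of the lesion carry rCBF <= core threshold and
prolonged Tmax so that perfusion volumetrics also have exact targets.
No skull is modelled (a brain-extracted NCCT is assumed), which keeps
left-right mirroring exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .densitometry import CTVolume, ROISet, mirror_roi
from .volumetrics import PerfusionMaps, volume_ml

__all__ = ["PhantomSpec", "PhantomBundle", "generate_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom case.

    Lengths: ``grid_shape`` in voxels, ``voxel_size_mm`` isotropic,
    ``lesion_center`` in voxel coordinates, ``lesion_radii`` in mm.
    Densities in HU. ``true_nwu_pct`` is the ground-truth water uptake of
    the lesion in percent.  Axis 0 is left-right; the midsagittal plane
    sits at the central sagittal slice.
    """

    grid_shape: tuple[int, int, int] = (61, 72, 40)
    voxel_size_mm: float = 2.0
    tissue_hu: float = 35.0
    csf_hu: float = 8.0
    calcification_hu: float = 120.0
    lesion_center: tuple[float, float, float] = (46.0, 36.0, 20.0)
    lesion_radii: tuple[float, float, float] = (16.0, 18.0, 14.0)
    true_nwu_pct: float = 7.2
    noise_sd_hu: float = 0.0
    seed: int = 0
    # concentric sub-region scales and perfusion values
    core_scale: float = 0.88          # rCBF-core ellipsoid, fraction of lesion radii
    hypoperfusion_scale: float = 1.6  # Tmax-lesion ellipsoid, fraction of lesion radii
    fiv_scale: float = 1.25           # follow-up infarct ellipsoid
    rcbf_core_pct: float = 10.0       # rCBF inside the core sub-region
    rcbf_normal_pct: float = 100.0
    tmax_lesion_s: float = 8.0
    tmax_normal_s: float = 2.0
    followup_nwu_pct: float = 20.0    # density deficit of the final infarct
    brain_radii_fraction: tuple[float, float, float] = (0.86, 0.9, 0.86)

    def __post_init__(self):
        if not 0 <= self.true_nwu_pct < 100:
            raise ValueError("true_nwu_pct must lie in [0, 100)")
        if not 20 < self.tissue_hu < 80:
            raise ValueError("tissue_hu must lie strictly inside (20, 80)")
        if self.csf_hu >= 20:
            raise ValueError("csf_hu must be below 20 HU")
        if self.calcification_hu <= 80:
            raise ValueError("calcification_hu must exceed 80 HU")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def lesion_hu(self) -> float:
        return self.tissue_hu * (1.0 - self.true_nwu_pct / 100.0)

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return (self.voxel_size_mm,) * 3

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class PhantomBundle:
    """All grids of one phantom case plus its ground truth."""

    admission_ct: CTVolume
    followup_ct: CTVolume
    perfusion: PerfusionMaps
    ischemic_mask: np.ndarray
    fiv_mask: np.ndarray
    brain_mask: np.ndarray
    truth: dict

    def rois(self) -> ROISet:
        """Lesion ROI and its contralateral mirror on the phantom grid."""
        return ROISet.from_lesion(self.ischemic_mask, axis=0)

    def save(self, out_dir: str | Path) -> None:
        """Write the bundle as NIfTI-1 volumes plus a JSON truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spacing = self.admission_ct.spacing_mm
        affine = np.diag(list(spacing) + [1.0])

        def _save(arr, name, dtype):
            nib.save(nib.Nifti1Image(np.asarray(arr).astype(dtype), affine),
                     str(out / name))

        _save(self.admission_ct.voxels, "admission_ct.nii", np.float32)
        _save(self.followup_ct.voxels, "followup_ct.nii", np.float32)
        _save(self.perfusion.rcbf_pct, "rcbf.nii", np.float32)
        _save(self.perfusion.tmax_s, "tmax.nii", np.float32)
        _save(self.ischemic_mask, "ischemic_mask.nii", np.uint8)
        _save(self.fiv_mask, "fiv_mask.nii", np.uint8)
        _save(self.brain_mask, "brain_mask.nii", np.uint8)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "PhantomBundle":
        p = Path(in_dir)

        def _arr(name):
            return np.asanyarray(nib.load(str(p / name)).dataobj).astype(np.float64)

        truth = json.loads((p / "truth.json").read_text())
        spacing = tuple(truth["spec"]["voxel_size_mm"] for _ in range(3))
        brain = _arr("brain_mask.nii").astype(bool)
        return cls(
            admission_ct=CTVolume(_arr("admission_ct.nii"), spacing),
            followup_ct=CTVolume(_arr("followup_ct.nii"), spacing),
            perfusion=PerfusionMaps(_arr("rcbf.nii"), _arr("tmax.nii"), brain, spacing),
            ischemic_mask=_arr("ischemic_mask.nii").astype(bool),
            fiv_mask=_arr("fiv_mask.nii").astype(bool),
            brain_mask=brain,
            truth=truth,
        )


def _ellipsoid(shape, center, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii_vox):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Rasterise a phantom case from its generative spec.

    Raises
    ------
    ValueError
        If the lesion crosses or touches the midsagittal plane (its mirror
        would overlap ischemia), extends beyond the brain, or its density
        falls below the 20 HU filter floor (densitometrically unmeasurable).
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    vs = spec.voxel_size_mm
    center = tuple((s - 1) / 2.0 for s in shape)
    brain_radii = tuple(f * (s - 1) / 2.0 for f, s in
                        zip(spec.brain_radii_fraction, shape))
    brain = _ellipsoid(shape, center, brain_radii)

    lesion_radii_vox = tuple(r / vs for r in spec.lesion_radii)
    lesion = _ellipsoid(shape, spec.lesion_center, lesion_radii_vox)
    if not lesion.any():
        raise ValueError("lesion rasterises to zero voxels")
    if not (lesion & ~brain).sum() == 0:
        raise ValueError("lesion extends beyond the brain / hemisphere")
    # mirror_roi raises if the lesion touches or crosses the midline
    mirror_roi(lesion, axis=0)

    if spec.lesion_hu < 20.0:
        raise ValueError(
            f"lesion density {spec.lesion_hu:.1f} HU falls below the 20 HU "
            "filter floor; phantom would be densitometrically unmeasurable"
        )

    # symmetric ventricles (CSF), clear of lesion and of its mirror
    mid = (shape[0] - 1) / 2.0
    vent_rad = (2.4, 4.5, 3.0)  # voxels
    offset = 4.5
    vent_l = _ellipsoid(shape, (mid - offset, center[1], center[2]), vent_rad)
    vent_r = _ellipsoid(shape, (mid + offset, center[1], center[2]), vent_rad)
    ventricles = (vent_l | vent_r) & brain
    if (ventricles & lesion).any():
        raise ValueError("lesion overlaps the ventricular CSF model")

    # confounder inclusions inside the lesion ROI
    csf_inc = _ellipsoid(shape, spec.lesion_center,
                         tuple(max(r * 0.18, 1.0) for r in lesion_radii_vox))
    calc_center = tuple(c + r * 0.5 for c, r in
                        zip(spec.lesion_center, lesion_radii_vox))
    calc_inc = _ellipsoid(shape, calc_center,
                          tuple(max(r * 0.12, 0.8) for r in lesion_radii_vox))
    csf_inc &= lesion
    calc_inc &= lesion & ~csf_inc

    admission = np.zeros(shape, dtype=np.float64)
    admission[brain] = spec.tissue_hu
    admission[lesion] = spec.lesion_hu
    admission[ventricles] = spec.csf_hu
    admission[csf_inc] = spec.csf_hu
    admission[calc_inc] = spec.calcification_hu

    fiv = _ellipsoid(shape, spec.lesion_center,
                     tuple(r * spec.fiv_scale for r in lesion_radii_vox)) & brain
    mirror_roi(fiv, axis=0)  # final infarct must stay in one hemisphere too
    followup = np.zeros(shape, dtype=np.float64)
    followup[brain] = spec.tissue_hu
    followup[fiv] = spec.tissue_hu * (1.0 - spec.followup_nwu_pct / 100.0)
    followup[ventricles] = spec.csf_hu
    followup[csf_inc] = spec.csf_hu
    followup[calc_inc] = spec.calcification_hu

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_hu > 0:
        admission = admission + rng.normal(0.0, spec.noise_sd_hu, shape)
        followup = followup + rng.normal(0.0, spec.noise_sd_hu, shape)

    core = _ellipsoid(shape, spec.lesion_center,
                      tuple(r * spec.core_scale for r in lesion_radii_vox)) & brain
    hypo = _ellipsoid(shape, spec.lesion_center,
                      tuple(r * spec.hypoperfusion_scale for r in lesion_radii_vox)) & brain
    rcbf = np.zeros(shape, dtype=np.float64)
    rcbf[brain] = spec.rcbf_normal_pct
    rcbf[core] = spec.rcbf_core_pct
    tmax = np.zeros(shape, dtype=np.float64)
    tmax[brain] = spec.tmax_normal_s
    tmax[hypo] = spec.tmax_lesion_s

    spacing = spec.spacing_mm
    pcore_ml = volume_ml(core, spacing)
    hypo_ml = volume_ml(hypo, spacing)
    fiv_ml = volume_ml(fiv, spacing)
    truth = {
        "spec": spec.to_dict(),
        "true_nwu_pct": spec.true_nwu_pct,
        "lesion_hu": spec.lesion_hu,
        "lesion_ml": volume_ml(lesion, spacing),
        "pcore_ml": pcore_ml,
        "hypoperfusion_ml": hypo_ml,
        "penumbra_ml": hypo_ml - pcore_ml,
        "fiv_ml": fiv_ml,
        "lesion_growth_ml": fiv_ml - pcore_ml,
        "overestimated": bool(fiv_ml - pcore_ml < -10.0),
    }
    return PhantomBundle(
        admission_ct=CTVolume(admission, spacing, midsagittal_axis=0),
        followup_ct=CTVolume(followup, spacing, midsagittal_axis=0),
        perfusion=PerfusionMaps(rcbf, tmax, brain, spacing),
        ischemic_mask=lesion,
        fiv_mask=fiv,
        brain_mask=brain,
        truth=truth,
    )
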