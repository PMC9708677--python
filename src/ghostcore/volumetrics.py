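"""Perfusion-threshold volumetrics, lesion growth, and core overestimation.

The CT-perfusion predicted ischemic core (pCore) is the brain volume with
relative cerebral blood flow at or below 20% of the contralateral normal
value.  Hypoperfused tissue is the volume with time-to-maximum (Tmax) of
at least 6 s; the mismatch (penumbra) is hypoperfusion minus pCore.
Lesion growth is the final infarct volume (FIV, segmented on follow-up CT)
minus pCore; growth more negative than -10 mL marks the admission pCore as
overestimated (the "ghost infarct core").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerfusionMaps",
    "VolumeSet",
    "volume_ml",
    "compute_pcore",
    "compute_penumbra",
    "lesion_growth",
    "classify_overestimation",
    "cubic_root_transform",
]

logger = logging.getLogger(__name__)

RCBF_CORE_THRESHOLD_PCT = 20.0
TMAX_HYPOPERFUSION_S = 6.0
OVERESTIMATION_CUTOFF_ML = -10.0


@dataclass(frozen=True)
class PerfusionMaps:
    """rCBF (% of contralateral) and Tmax (s) grids with a brain mask."""

    rcbf_pct: np.ndarray
    tmax_s: np.ndarray
    brain_mask: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        rcbf = np.asarray(self.rcbf_pct, dtype=float)
        tmax = np.asarray(self.tmax_s, dtype=float)
        brain = np.asarray(self.brain_mask).astype(bool)
        if not (rcbf.shape == tmax.shape == brain.shape):
            raise ValueError("rCBF, Tmax and brain mask shapes differ")
        if np.any(rcbf[brain] < 0) or np.any(tmax[brain] < 0):
            raise ValueError("rCBF and Tmax must be non-negative inside the brain")
        sp = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in sp):
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "rcbf_pct", rcbf)
        object.__setattr__(self, "tmax_s", tmax)
        object.__setattr__(self, "brain_mask", brain)
        object.__setattr__(self, "spacing_mm", sp)


@dataclass(frozen=True)
class VolumeSet:
    """Per-case perfusion and follow-up volumetrics (all in mL)."""

    pcore_ml: float
    hypoperfusion_ml: float
    penumbra_ml: float
    fiv_ml: float
    lesion_growth_ml: float
    overestimated: bool

    def to_dict(self) -> dict:
        return {
            "pcore_ml": self.pcore_ml,
            "hypoperfusion_ml": self.hypoperfusion_ml,
            "penumbra_ml": self.penumbra_ml,
            "fiv_ml": self.fiv_ml,
            "lesion_growth_ml": self.lesion_growth_ml,
            "overestimated": self.overestimated,
        }


def volume_ml(mask: np.ndarray, spacing_mm) -> float:
    """Volume of a binary mask in millilitres (voxel count x voxel volume)."""
    sp = tuple(float(s) for s in spacing_mm)
    if any(s <= 0 for s in sp):
        raise ValueError("spacing must be strictly positive")
    n = int(np.count_nonzero(np.asarray(mask)))
    return n * float(np.prod(sp)) / 1000.0


def compute_pcore(maps: PerfusionMaps, rcbf_threshold: float = RCBF_CORE_THRESHOLD_PCT) -> float:
    """Predicted core volume: brain voxels with rCBF <= threshold (% of contralateral)."""
    if not 0 < rcbf_threshold <= 100:
        raise ValueError("rCBF threshold must lie in (0, 100]")
    core = maps.brain_mask & (maps.rcbf_pct <= rcbf_threshold)
    return volume_ml(core, maps.spacing_mm)


def compute_penumbra(maps: PerfusionMaps, pcore_ml: float,
                     tmax_threshold: float = TMAX_HYPOPERFUSION_S) -> tuple[float, float]:
    """Hypoperfusion (Tmax >= threshold) and mismatch volumes in mL.

    Penumbra = hypoperfusion - pCore, floored at zero (with a warning) if
    the predicted core extends beyond the Tmax lesion.
    """
    if pcore_ml < 0:
        raise ValueError("pcore_ml must be non-negative")
    hypo = maps.brain_mask & (maps.tmax_s >= tmax_threshold)
    hypoperfusion_ml = volume_ml(hypo, maps.spacing_mm)
    penumbra = hypoperfusion_ml - pcore_ml
    if penumbra < 0:
        logger.warning(
            "negative mismatch volume (%.1f mL): pCore exceeds the Tmax lesion; floored at 0",
            penumbra,
        )
        penumbra = 0.0
    return hypoperfusion_ml, penumbra


def lesion_growth(fiv_ml: float, pcore_ml: float) -> float:
    """Lesion growth in mL: final infarct volume minus predicted core (signed)."""
    if fiv_ml < 0 or pcore_ml < 0:
        raise ValueError("volumes must be non-negative")
    return float(fiv_ml) - float(pcore_ml)


def classify_overestimation(growth_ml: float,
                            cutoff_ml: float = OVERESTIMATION_CUTOFF_ML) -> bool:
    """True iff lesion growth is negative by strictly more than 10 mL."""
    if not np.isfinite(growth_ml):
        raise ValueError("growth must be finite")
    return bool(growth_ml < cutoff_ml)


def cubic_root_transform(growth_ml):
    """Signed cube root, sign(x)*|x|^(1/3).

    The variance-stabilising transform applied to lesion growth before
    linear modelling; the signed extension keeps the map odd and monotone
    for the negative-growth (overestimated) cases.
    """
    x = np.asarray(growth_ml, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("growth must be finite")
    out = np.cbrt(x)
    return float(out) if np.isscalar(growth_ml) or out.ndim == 0 else out
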