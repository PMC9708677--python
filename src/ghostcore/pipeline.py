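"""End-to-end orchestration: per-case measurement and study-level tables.

``run_case`` measures one imaging case (NWU densitometry plus perfusion
and follow-up volumetrics) from NIfTI inputs on disk; ``run_study``
produces the study-level tables — baseline descriptives stratified by
core overestimation, univariable and multivariable relative-risk tables
for overestimation and 90-day good outcome, the linear model of cube-root
lesion growth, and the 50 mL pCore-stratified sensitivity analysis — from
a cohort CSV or a freshly simulated cohort.  Every output embeds the
configuration hash, seed, and package version for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import EffectConfig, simulate_cohort
from .densitometry import CTVolume, ROISet, compute_nwu
from .describe import describe_cohort
from .regression import build_multivariable, fit_linear, fit_rr, stratified_sensitivity
from .volumetrics import (
    PerfusionMaps,
    classify_overestimation,
    compute_pcore,
    compute_penumbra,
    cubic_root_transform,
    lesion_growth,
    volume_ml,
)

__all__ = ["PipelineConfig", "run_case", "run_study"]

logger = logging.getLogger(__name__)

#: Table-2 candidate predictors of the binary outcomes
RISK_PREDICTORS = [
    "age", "sex_female", "nihss", "aspects", "pcore_ml", "nwu_pct",
    "iv_alteplase", "onset_to_imaging_min", "onset_to_recanalization_min",
    "reperfusion_success",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, model options and seed for one analysis run."""

    hu_lo: float = 20.0
    hu_hi: float = 80.0
    rcbf_threshold_pct: float = 20.0
    tmax_threshold_s: float = 6.0
    overestimation_cutoff_ml: float = -10.0
    stratify_cutoff_ml: float = 50.0
    rr_family: str = "log-binomial"
    alpha: float = 0.05
    statistic: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if not self.hu_lo < self.hu_hi:
            raise ValueError("hu_lo must be below hu_hi")
        if not 0 < self.rcbf_threshold_pct <= 100:
            raise ValueError("rcbf threshold must lie in (0, 100]")
        if self.tmax_threshold_s < 0 or self.stratify_cutoff_ml < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "software_version": __version__}


def _check_geometry(shapes: dict[str, tuple]) -> None:
    ref_name, ref_shape = next(iter(shapes.items()))
    for name, shape in shapes.items():
        if shape != ref_shape:
            raise ValueError(
                f"geometry mismatch between '{ref_name}' {ref_shape} and "
                f"'{name}' {shape}")


def run_case(config: PipelineConfig, case_dir: str | Path,
             case_id: str | None = None) -> dict:
    """Measure one case directory of NIfTI volumes into a flat result row.

    Expects ``admission_ct.nii`` and ``ischemic_mask.nii``; uses
    ``rcbf.nii``/``tmax.nii``/``brain_mask.nii`` for perfusion volumetrics
    and ``fiv_mask.nii`` for lesion growth when present.  Missing
    follow-up leaves the growth fields NaN while NWU is still emitted.
    """
    case_dir = Path(case_dir)
    case_id = case_id or case_dir.name
    ct = CTVolume.from_nifti(case_dir / "admission_ct.nii")
    lesion = CTVolume.from_nifti(case_dir / "ischemic_mask.nii").voxels.astype(bool)
    _check_geometry({"admission_ct": ct.shape, "ischemic_mask": lesion.shape})

    rois = ROISet.from_lesion(lesion, axis=ct.midsagittal_axis,
                              plane_index=ct.midsagittal_index)
    nwu = compute_nwu(ct, rois, hu_lo=config.hu_lo, hu_hi=config.hu_hi,
                      statistic=config.statistic)
    row: dict = {"case_id": case_id, **nwu.to_dict()}

    rcbf_p, tmax_p = case_dir / "rcbf.nii", case_dir / "tmax.nii"
    if rcbf_p.exists() and tmax_p.exists():
        rcbf = CTVolume.from_nifti(rcbf_p)
        tmax = CTVolume.from_nifti(tmax_p)
        brain_p = case_dir / "brain_mask.nii"
        brain = (CTVolume.from_nifti(brain_p).voxels.astype(bool)
                 if brain_p.exists() else np.ones(rcbf.shape, dtype=bool))
        _check_geometry({"admission_ct": ct.shape, "rcbf": rcbf.shape,
                         "tmax": tmax.shape, "brain_mask": brain.shape})
        maps = PerfusionMaps(rcbf.voxels, tmax.voxels, brain, rcbf.spacing_mm)
        pcore = compute_pcore(maps, config.rcbf_threshold_pct)
        hypo, penumbra = compute_penumbra(maps, pcore, config.tmax_threshold_s)
        row.update(pcore_ml=pcore, hypoperfusion_ml=hypo, penumbra_ml=penumbra)
    else:
        row.update(pcore_ml=np.nan, hypoperfusion_ml=np.nan, penumbra_ml=np.nan)

    fiv_p = case_dir / "fiv_mask.nii"
    if fiv_p.exists() and np.isfinite(row["pcore_ml"]):
        fiv_vol = CTVolume.from_nifti(fiv_p)
        _check_geometry({"admission_ct": ct.shape, "fiv_mask": fiv_vol.shape})
        fiv_ml = volume_ml(fiv_vol.voxels.astype(bool), fiv_vol.spacing_mm)
        growth = lesion_growth(fiv_ml, row["pcore_ml"])
        row.update(
            fiv_ml=fiv_ml,
            lesion_growth_ml=growth,
            cbrt_growth=cubic_root_transform(growth),
            overestimated=classify_overestimation(
                growth, config.overestimation_cutoff_ml),
        )
    else:
        logger.info("case %s: no follow-up/perfusion inputs; growth fields missing",
                    case_id)
        row.update(fiv_ml=np.nan, lesion_growth_ml=np.nan, cbrt_growth=np.nan,
                   overestimated=np.nan)
    row.update(config.provenance())
    return row


def _augment(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derived analysis columns: female indicator, cube-root growth."""
    df = cohort.copy()
    if "sex" in df.columns and "sex_female" not in df.columns:
        df["sex_female"] = df["sex"].map({"F": 1.0, "M": 0.0})
    if "lesion_growth_ml" in df.columns and "cbrt_growth" not in df.columns:
        df["cbrt_growth"] = cubic_root_transform(
            df["lesion_growth_ml"].to_numpy(dtype=float))
    return df


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def run_study(config: PipelineConfig, cohort: pd.DataFrame | None = None,
              effect_config: EffectConfig | None = None,
              out_dir: str | Path | None = None) -> dict:
    """Produce the full study results bundle from a cohort table.

    If ``cohort`` is None, a cohort is simulated from ``effect_config``
    (default configuration, seeded from ``config.seed``).  Returns a dict
    of DataFrames and metadata; if ``out_dir`` is given, also writes
    CSV tables and a JSON bundle there.
    """
    if cohort is None:
        effect_config = effect_config or EffectConfig(seed=config.seed)
        cohort = simulate_cohort(effect_config)
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least 2 cases")
    df = _augment(cohort)

    table1 = describe_cohort(df.drop(columns=["sex_female", "cbrt_growth"],
                                     errors="ignore"),
                             group_by="overestimated")

    preds = [p for p in RISK_PREDICTORS if p in df.columns]
    uni_over = fit_rr(df, "overestimated", preds, family=config.rr_family,
                      alpha=config.alpha)
    multi_over_preds = build_multivariable(uni_over, alpha=config.alpha)
    multi_over = (fit_rr(df, "overestimated", multi_over_preds, multivariable=True,
                         family=config.rr_family, alpha=config.alpha)
                  if multi_over_preds else [])

    uni_good = fit_rr(df, "good_outcome", preds, family=config.rr_family,
                      alpha=config.alpha)
    multi_good_preds = build_multivariable(uni_good, alpha=config.alpha,
                                           forced=("sex_female",))
    multi_good = (fit_rr(df, "good_outcome", multi_good_preds, multivariable=True,
                         family=config.rr_family, alpha=config.alpha)
                  if multi_good_preds else [])

    uni_growth = fit_linear(df, "cbrt_growth", preds, alpha=config.alpha)
    multi_growth_preds = build_multivariable(uni_growth, alpha=config.alpha)
    multi_growth = (fit_linear(df, "cbrt_growth", multi_growth_preds,
                               multivariable=True, alpha=config.alpha)
                    if multi_growth_preds else [])

    strat = stratified_sensitivity(df, "overestimated", preds,
                                   cutoff_ml=config.stratify_cutoff_ml,
                                   kind="rr", family=config.rr_family,
                                   alpha=config.alpha)

    bundle = {
        "table1": table1,
        "table2_overestimation": pd.concat(
            [_results_frame(uni_over), _results_frame(multi_over)],
            ignore_index=True),
        "table2_good_outcome": pd.concat(
            [_results_frame(uni_good), _results_frame(multi_good)],
            ignore_index=True),
        "table3_growth": pd.concat(
            [_results_frame(uni_growth), _results_frame(multi_growth)],
            ignore_index=True),
        "stratified_lt": _results_frame(strat["lt"]),
        "stratified_ge": _results_frame(strat["ge"]),
        "provenance": config.provenance(),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out / f"{name}.csv", index=False)
        meta = {"provenance": bundle["provenance"],
                "config": config.to_dict(),
                "n_cohort": int(len(cohort))}
        (out / "results.json").write_text(json.dumps(meta, indent=2))
        df.to_csv(out / "cohort.csv", index=False)
    return bundle
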