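"""Group-wise descriptive comparison of a cohort table.

Continuous variables are summarised as median (IQR) when Shapiro-Wilk
rejects normality at 0.05, otherwise mean (SD), and compared between
groups with the Wilcoxon rank-sum test.  Categorical/boolean variables
are summarised as counts and proportions.  Per-field n is reported
whenever values are missing, mirroring registry-style baseline tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["describe_cohort"]

_SKIP_COLS = {"case_id", "p_overest_true"}


def _is_categorical(s: pd.Series) -> bool:
    if s.dtype == bool or s.dtype == object:
        return True
    vals = s.dropna().unique()
    return set(np.unique(vals)).issubset({0, 1, 0.0, 1.0, True, False})


def describe_cohort(cohort: pd.DataFrame, group_by: str = "overestimated",
                    shapiro_alpha: float = 0.05) -> pd.DataFrame:
    """Baseline-characteristics table stratified by a binary grouping field.

    Returns one row per variable with per-group summaries, per-group n,
    and a Wilcoxon rank-sum p-value for continuous variables.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    if group_by not in cohort.columns:
        raise KeyError(f"no grouping column '{group_by}'")
    g = cohort[group_by].dropna().astype(bool)
    groups = {True: cohort.loc[g[g].index], False: cohort.loc[g[~g].index]}
    if any(sub.empty for sub in groups.values()):
        raise ValueError("both groups must be non-empty")

    rows = []
    for col in cohort.columns:
        if col in _SKIP_COLS or col == group_by:
            continue
        s = cohort[col]
        row: dict = {"variable": col}
        if _is_categorical(s):
            row["kind"] = "categorical"
            for flag, sub in groups.items():
                vals = sub[col].dropna()
                tag = "yes" if flag else "no"
                if s.dtype == object:
                    top = vals.value_counts(normalize=True).to_dict()
                    row[f"summary_{tag}"] = "; ".join(
                        f"{k}: {v:.1%}" for k, v in sorted(top.items()))
                else:
                    n_pos = int(vals.astype(bool).sum())
                    prop = n_pos / len(vals) if len(vals) else np.nan
                    row[f"summary_{tag}"] = f"{n_pos} ({prop:.1%})"
                row[f"n_{tag}"] = int(len(vals))
            row["p_value"] = np.nan
        else:
            vals_all = pd.to_numeric(s, errors="coerce").dropna()
            if vals_all.nunique() < 3 or len(vals_all) < 3:
                normal = False
            else:
                normal = stats.shapiro(vals_all.sample(
                    min(len(vals_all), 5000), random_state=0)).pvalue >= shapiro_alpha
            row["kind"] = "normal" if normal else "non-normal"
            group_vals = {}
            for flag, sub in groups.items():
                vals = pd.to_numeric(sub[col], errors="coerce").dropna()
                tag = "yes" if flag else "no"
                group_vals[flag] = vals
                if normal:
                    row[f"summary_{tag}"] = f"{vals.mean():.1f} ({vals.std():.1f})"
                else:
                    q1, q2, q3 = vals.quantile([0.25, 0.5, 0.75])
                    row[f"summary_{tag}"] = f"{q2:.1f} ({q1:.1f}-{q3:.1f})"
                row[f"n_{tag}"] = int(len(vals))
            if all(len(v) for v in group_vals.values()):
                row["p_value"] = float(stats.ranksums(
                    group_vals[True], group_vals[False]).pvalue)
            else:
                row["p_value"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    # report n only where values are missing, as baseline tables do
    total = {True: len(groups[True]), False: len(groups[False])}
    for tag, flag in (("yes", True), ("no", False)):
        full = out[f"n_{tag}"] == total[flag]
        out.loc[full, f"n_{tag}"] = -1
        out[f"n_{tag}"] = out[f"n_{tag}"].replace(-1, np.nan)
    return out
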