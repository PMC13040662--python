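"""Cohort summary tables: clinical characteristics by case status.

Continuous biomarkers are summarized by geometric mean and geometric CV
(computed on the log scale: GM = exp(mean(log x)),
GCV% = 100 * sqrt(exp(var(log x)) - 1)) and compared between cases and
controls with a two-sample t-test on the log-transformed values.  Binary
traits (atopy) are summarized as counts and percentages with a chi-square
test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def geometric_mean(x) -> float:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    return float(np.exp(np.mean(np.log(x))))


def geometric_cv(x) -> float:
    """Geometric coefficient of variation, percent."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    return float(100.0 * np.sqrt(np.exp(np.var(np.log(x), ddof=1)) - 1.0))


def percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage rounded to the printed precision of a summary table."""
    return round(100.0 * numerator / denominator, digits)


def binary_trait_summary(flags: pd.Series, case: pd.Series) -> dict:
    """Counts/percentages of a nullable-boolean trait by case status."""
    obs = flags.notna()
    f = flags[obs].astype(bool)
    y = case[obs].astype(bool)
    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    k_case = int((f & y).sum())
    k_ctrl = int((f & ~y).sum())
    table = np.array([[k_case, n_case - k_case], [k_ctrl, n_ctrl - k_ctrl]])
    p = stats.chi2_contingency(table)[1] if table.min() >= 0 else np.nan
    return {
        "pct_cases": percent(k_case, n_case),
        "pct_controls": percent(k_ctrl, n_ctrl),
        "pct_overall": percent(k_case + k_ctrl, n_case + n_ctrl),
        "n_cases": n_case,
        "n_controls": n_ctrl,
        "p": float(p),
    }


def biomarker_summary(values: pd.Series, case: pd.Series) -> dict:
    """Geometric mean/CV by case status with a log-scale two-sample t-test."""
    obs = values.notna()
    v = values[obs].to_numpy(dtype=float)
    y = case[obs].to_numpy(dtype=bool)
    res = stats.ttest_ind(np.log(v[y]), np.log(v[~y]), equal_var=True)
    return {
        "geo_mean_cases": geometric_mean(v[y]),
        "geo_cv_cases": geometric_cv(v[y]),
        "geo_mean_controls": geometric_mean(v[~y]),
        "geo_cv_controls": geometric_cv(v[~y]),
        "geo_mean_overall": geometric_mean(v),
        "geo_cv_overall": geometric_cv(v),
        "p": float(res.pvalue),
        "n_missing": int((~obs).sum()),
    }


def summarize_cohort(cohort: pd.DataFrame, outcome_col: str = "asthma",
                     biomarkers: list[str] = ("tige", "sige", "eos", "neut")) -> pd.DataFrame:
    """Clinical-characteristics table (cases vs controls vs overall)."""
    from .mediation import define_atopy

    case = cohort[outcome_col] == 1
    rows = []
    rows.append({"trait": "age_mean_cases", "value": cohort.loc[case, "age"].mean()})
    rows.append({"trait": "age_mean_controls", "value": cohort.loc[~case, "age"].mean()})
    if "sex" in cohort:
        rows.append({"trait": "pct_female_overall",
                     "value": percent(int((cohort["sex"] == "F").sum()), len(cohort))})
    if {"tige", "sige"} <= set(cohort.columns):
        atopy = define_atopy(cohort["tige"], cohort["sige"])
        summ = binary_trait_summary(atopy, case)
        for k, v in summ.items():
            rows.append({"trait": f"atopy_{k}", "value": v})
    for bm in biomarkers:
        if bm not in cohort:
            continue
        summ = biomarker_summary(cohort[bm], case)
        for k, v in summ.items():
            rows.append({"trait": f"{bm}_{k}", "value": v})
    return pd.DataFrame(rows)
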