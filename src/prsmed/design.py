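"""Regression design-matrix construction from cohort tables.

Numeric covariates enter as-is; string/categorical covariates are
reference-coded with the alphabetically first level as reference.  An
intercept column is always prepended.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DesignError


def build_design(df: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    """Return (X, column_names) with an intercept as the first column.

    Rows must already be complete cases; NaN anywhere raises.
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in df.columns:
            raise DesignError(f"covariate {cov!r} not in table")
        s = df[cov]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            v = s.to_numpy(dtype=float)
            if np.isnan(v).any():
                raise DesignError(f"covariate {cov!r} has missing values")
            cols.append(v)
            names.append(cov)
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:  # first (alphabetical) level is reference
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    return X, names


def drop_constant_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop non-intercept columns with zero variance; returns the dropped names."""
    keep = [0]
    dropped = []
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            dropped.append(names[j])
        else:
            keep.append(j)
    return X[:, keep], [names[j] for j in keep], dropped
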