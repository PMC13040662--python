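"""Expression-module association and mediation analyses.

Module scores are generic continuous per-sample summaries of co-expression
modules (eigengene-like); their construction is upstream of this package.
Two analyses are provided: a per-module linear association with the PRS
adjusted for clinical plus technical covariates, and a per-module percent
mediation of the PRS-asthma relationship on the current-asthma subset
(controls plus cases with severity index CASI >= 1).  The module panel is
BH-corrected as its own family, separate from the biomarker panel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .design import build_design, drop_constant_columns
from .errors import DataError, DesignError, PanelError, SubsetError
from .glm import fit_linear
from .mediation import (
    BootstrapConfig,
    MEDIATION_COVARIATES,
    bh_adjust,
    bootstrap_mediation,
)

logger = logging.getLogger(__name__)

# association covariates include the RNA-seq technical terms
EXPRESSION_COVARIATES = ["age", "sex", "batch", "site", "RIN", "GC", "PC1", "PC2"]


def subset_current_asthma(cohort: pd.DataFrame, outcome_col: str = "asthma",
                          casi_col: str = "casi") -> pd.DataFrame:
    """Controls plus cases with CASI >= 1 (current asthma).

    Cases with CASI < 1 or missing CASI are dropped, with a logged count.
    """
    is_case = cohort[outcome_col] == 1
    keep_case = is_case & (cohort[casi_col] >= 1)
    dropped = int((is_case & ~keep_case).sum())
    out = cohort[~is_case | keep_case].reset_index(drop=True)
    logger.info("current-asthma subset: dropped %d of %d cases",
                dropped, int(is_case.sum()))
    if not (out[outcome_col] == 1).any():
        raise SubsetError("no cases remain in the current-asthma subset")
    return out


def module_prs_association(
    modules: list[str],
    prs_z,
    cohort: pd.DataFrame,
    covariates: list[str] = EXPRESSION_COVARIATES,
) -> pd.DataFrame:
    """Linear regression of each module score on the PRS with covariates.

    Complete cases per module; BH correction across the module family.
    Constant covariate columns (e.g. a single-level batch) are dropped with
    a warning rather than failing the fit.
    """
    if not modules:
        raise PanelError("empty module list")
    df = cohort.reset_index(drop=True).copy()
    df["_prs"] = np.asarray(prs_z, dtype=float)
    rows = []
    for mod in modules:
        cc = df.dropna(subset=[mod, "_prs"] + covariates)
        X0, names = build_design(cc, covariates)
        X = np.column_stack([X0, cc["_prs"].to_numpy()])
        names = names + ["prs_z"]
        X, names, dropped = drop_constant_columns(X, names)
        if dropped:
            logger.warning("module %s: dropped constant columns %s", mod, dropped)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError(f"module {mod}: rank-deficient design")
        yv = cc[mod].to_numpy(dtype=float)
        beta = fit_linear(yv, X)
        resid = yv - X @ beta
        dof = len(cc) - X.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        j = names.index("prs_z")
        se = np.sqrt(cov[j, j])
        tstat = beta[j] / se
        # clamp underflowed p-values to the smallest positive float so the
        # BH step (defined on (0,1]) accepts them
        p = max(2 * stats.t.sf(abs(tstat), dof), np.finfo(float).tiny)
        rows.append((mod, beta[j], se, p, len(cc)))
    out = pd.DataFrame(rows, columns=["module", "beta", "se", "p", "n"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def module_mediation_panel(
    modules: list[str],
    prs_z,
    cohort_current: pd.DataFrame,
    config: BootstrapConfig,
    covariates: list[str] = MEDIATION_COVARIATES,
    outcome_col: str = "asthma",
) -> pd.DataFrame:
    """Percent mediation of the PRS-asthma relation through each module.

    Module scores are re-standardized within the analysis subset.  Failures
    (e.g. a module collinear with a covariate) are isolated per module and
    reported in an ``error`` column; BH correction spans the modules that
    succeeded.
    """
    if not modules:
        raise PanelError("empty module table")
    seeds = np.random.SeedSequence(config.seed).generate_state(len(modules))
    results = []
    failures = []
    for mod, seed in zip(modules, seeds):
        try:
            vals = cohort_current[mod].to_numpy(dtype=float)
            sd = np.nanstd(vals, ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise DataError(f"module {mod} is constant")
            med_z = (vals - np.nanmean(vals)) / sd
            cfg = BootstrapConfig(n_reps=config.n_reps, seed=int(seed % (2**31)),
                                  ci_level=config.ci_level,
                                  max_refit_failures=config.max_refit_failures)
            res = bootstrap_mediation(
                cohort_current[outcome_col], prs_z, med_z, cohort_current,
                cfg, covariates=covariates,
            )
            res.mediator = mod
            results.append(res)
        except (DataError, DesignError, ValueError) as exc:
            logger.warning("module %s mediation failed: %s", mod, exc)
            failures.append({"mediator": mod, "error": str(exc)})
    if not results:
        raise PanelError("all modules failed mediation")
    padj = bh_adjust([r.p for r in results])
    for r, pa in zip(results, padj):
        r.p_adj = float(pa)
    ok = pd.DataFrame([vars(r) for r in results])
    ok["error"] = ""
    if failures:
        ok = pd.concat([ok, pd.DataFrame(failures)], ignore_index=True)
    return ok.sort_values("pm", ascending=False).reset_index(drop=True)
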