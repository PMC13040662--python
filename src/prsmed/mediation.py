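"""Three-regression percent-mediation with percentile-bootstrap inference.

The mediation statistic follows the difference-in-coefficients construction
for a binary outcome: with standardized exposure (PRS Z-score) and
standardized mediator,

    a  : linear regression    mediator_z ~ prs_z + covariates
    c  : logistic regression  outcome ~ prs_z + covariates
    c' : logistic regression  outcome ~ prs_z + mediator_z + covariates

and percent mediation PM = (c - c') / c on the log-odds scale.  Confidence
intervals and p-values come from a nonparametric bootstrap that resamples
whole rows and recomputes PM per resample; multiple mediators in a panel are
corrected by Benjamini-Hochberg.  Biomarker mediators are prepared by
half-detection-limit substitution for left-censored assays, an optional
additive offset (e.g. +1 for cell counts), a natural-log transform, and
Z-scoring.

PM is a statistical decomposition, not a causal effect: it quantifies how
much of the exposure-outcome coefficient is captured by the mediator, and
is reported without truncation to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .design import build_design
from .errors import DataError, DesignError, PanelError
from .glm import fit_linear, fit_logistic

logger = logging.getLogger(__name__)

MEDIATION_COVARIATES = ["age", "sex", "site", "PC1", "PC2"]

ATOPY_TIGE_THRESHOLD = 100.0  # kU/L, strict >
ATOPY_SIGE_THRESHOLD = 0.36   # PAU/L, inclusive >=


@dataclass
class MediatorSpec:
    """How to prepare one mediator column before analysis.

    detection_limit: assay lower limit; observed values below it are replaced
    by half the limit before the log transform.  offset: added before the log
    (e.g. +1 for cell counts that can be zero).
    """

    name: str
    detection_limit: float | None = None
    offset: float = 0.0

    def __post_init__(self):
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.detection_limit is not None and self.detection_limit <= 0:
            raise ValueError("detection_limit must be > 0")


@dataclass
class BootstrapConfig:
    n_reps: int = 10_000
    seed: int | None = None
    ci_level: float = 0.95
    max_refit_failures: float = 0.1

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0,1)")


@dataclass
class MediationResult:
    mediator: str
    a: float = np.nan
    c: float = np.nan
    c_prime: float = np.nan
    pm: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    p_adj: float = np.nan
    n_used: int = 0
    n_boot_failed: int = 0


def prepare_mediator(values, spec: MediatorSpec) -> np.ndarray:
    """Half-limit substitution, offset, natural log, Z-score.

    Missing entries propagate as NaN; standardization (mean 0, sd 1 with
    n-1 denominator) is over non-missing entries only.
    """
    v = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(v)
    if spec.detection_limit is not None:
        v[obs & (v < spec.detection_limit)] = spec.detection_limit / 2.0
    v = v + spec.offset
    bad = obs & (v <= 0)
    if bad.any():
        idx = np.flatnonzero(bad)[:5].tolist()
        raise DataError(
            f"{spec.name}: non-positive value(s) after offset at log step, "
            f"sample indices {idx}"
        )
    logv = np.where(obs, np.log(np.where(obs, v, 1.0)), np.nan)
    sd = np.nanstd(logv, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DataError(f"{spec.name}: constant after transform, cannot standardize")
    return (logv - np.nanmean(logv)) / sd


def define_atopy(tige, sige) -> pd.Series:
    """Allergic sensitization: tIgE > 100 kU/L and/or sIgE >= 0.36 PAU/L.

    A sample with one missing marker is classified from the other; missing
    both yields a missing value (pandas nullable boolean).
    """
    t = pd.Series(np.asarray(tige, dtype=float))
    s = pd.Series(np.asarray(sige, dtype=float))
    t_pos = t > ATOPY_TIGE_THRESHOLD
    s_pos = s >= ATOPY_SIGE_THRESHOLD
    out = (t_pos | s_pos).astype("boolean")
    out[t.isna() & s.isna()] = pd.NA
    return out


def _pm_from_arrays(y, prs, med, Xcov, beta_c=None, beta_cp=None,
                    check_rank=False, rescale=False):
    """Compute (a, c, c_prime, pm, converged) on prepared numpy arrays.

    Xcov includes the intercept.  beta_c/beta_cp provide warm starts for the
    two logistic fits (used heavily by the bootstrap).
    """
    Xc = np.column_stack([Xcov, prs])
    Xcp = np.column_stack([Xcov, prs, med])
    a = fit_linear(med, Xc)[-1]
    fc = fit_logistic(y, Xc, beta0=beta_c, check_rank=check_rank)
    fcp = fit_logistic(y, Xcp, beta0=beta_cp, check_rank=check_rank)
    c = fc.params[-1]
    cp = fcp.params[-2]
    if rescale:
        # MacKinnon-Dwyer: put c and c' on the common latent-outcome scale
        # y* with var = var(linear predictor) + pi^2/3
        s2_logit = np.pi**2 / 3.0
        c = c / np.sqrt(np.var(Xc @ fc.params, ddof=1) + s2_logit)
        cp = cp / np.sqrt(np.var(Xcp @ fcp.params, ddof=1) + s2_logit)
    converged = fc.converged and fcp.converged
    if abs(c) < 1e-10:
        return a, c, cp, np.nan, False, fc.params, fcp.params
    return a, c, cp, (c - cp) / c, converged, fc.params, fcp.params


def mediation_point_estimate(
    outcome,
    prs_z,
    mediator_z,
    cohort: pd.DataFrame,
    covariates: list[str] = MEDIATION_COVARIATES,
    rescale: bool = False,
) -> MediationResult:
    """Point estimates of the a, c, c' paths and PM on complete cases.

    All three regressions are fit on the identical listwise-deleted sample.
    """
    df = cohort.reset_index(drop=True).copy()
    df["_y"] = np.asarray(outcome, dtype=float)
    df["_prs"] = np.asarray(prs_z, dtype=float)
    df["_med"] = np.asarray(mediator_z, dtype=float)
    cc = df.dropna(subset=["_y", "_prs", "_med"] + covariates)
    y = cc["_y"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome needs both classes after listwise deletion")
    Xcov, _ = build_design(cc, covariates)
    prs = cc["_prs"].to_numpy()
    med = cc["_med"].to_numpy()
    # rank check once on the widest design; bootstrap refits skip it
    Xfull = np.column_stack([Xcov, prs, med])
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        raise DesignError("collinear design (mediator, PRS, covariates)")
    a, c, cp, pm, converged, _, _ = _pm_from_arrays(
        y, prs, med, Xcov, check_rank=False, rescale=rescale
    )
    if np.isnan(pm):
        raise ValueError("total effect c is numerically zero; PM undefined")
    if not converged:
        logger.warning("point-estimate logistic fit did not converge")
    return MediationResult(
        mediator="", a=float(a), c=float(c), c_prime=float(cp),
        pm=float(pm), n_used=len(cc),
    )


def bootstrap_mediation(
    outcome,
    prs_z,
    mediator_z,
    cohort: pd.DataFrame,
    config: BootstrapConfig,
    covariates: list[str] = MEDIATION_COVARIATES,
    rescale: bool = False,
) -> MediationResult:
    """Percentile-bootstrap CI and p-value for PM.

    Whole rows (cases and controls pooled) are resampled with replacement
    ``n_reps`` times; PM is recomputed per resample.  The CI is the
    (alpha/2, 1-alpha/2) percentile pair, and the two-sided p-value is
    2*min(#{pm* <= 0}, #{pm* >= 0})/B, floored at 1/B.  Resamples with
    non-convergent or undefined fits are excluded and counted.
    """
    alpha = 1.0 - config.ci_level
    if config.n_reps < int(np.ceil(2.0 / alpha)):
        raise ValueError(
            f"n_reps={config.n_reps} too small for ci_level={config.ci_level}"
        )
    result = mediation_point_estimate(
        outcome, prs_z, mediator_z, cohort, covariates, rescale=rescale
    )
    # rebuild the complete-case arrays once for the resampling loop
    df = cohort.reset_index(drop=True).copy()
    df["_y"] = np.asarray(outcome, dtype=float)
    df["_prs"] = np.asarray(prs_z, dtype=float)
    df["_med"] = np.asarray(mediator_z, dtype=float)
    cc = df.dropna(subset=["_y", "_prs", "_med"] + covariates)
    y = cc["_y"].to_numpy()
    Xcov, _ = build_design(cc, covariates)
    prs = cc["_prs"].to_numpy()
    med = cc["_med"].to_numpy()
    n = y.size

    # warm starts from the full-data fits
    _, _, _, _, _, beta_c, beta_cp = _pm_from_arrays(y, prs, med, Xcov,
                                                     rescale=rescale)
    rng = np.random.default_rng(config.seed)
    pms = np.empty(config.n_reps)
    n_failed = 0
    kept = 0
    for _ in range(config.n_reps):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            n_failed += 1
            continue
        try:
            _, _, _, pm_b, conv, _, _ = _pm_from_arrays(
                yb, prs[idx], med[idx], Xcov[idx], beta_c=beta_c,
                beta_cp=beta_cp, rescale=rescale
            )
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
        if not conv or not np.isfinite(pm_b):
            n_failed += 1
            continue
        pms[kept] = pm_b
        kept += 1
    if n_failed > config.max_refit_failures * config.n_reps:
        raise ValueError(
            f"{n_failed}/{config.n_reps} bootstrap refits failed "
            f"(> max_refit_failures={config.max_refit_failures})"
        )
    pms = pms[:kept]
    lo, hi = np.percentile(pms, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    B = config.n_reps
    p = 2.0 * min((pms <= 0).sum(), (pms >= 0).sum()) / B
    p = min(1.0, max(p, 1.0 / B))
    result.ci_low = float(lo)
    result.ci_high = float(hi)
    result.p = float(p)
    result.n_boot_failed = n_failed
    return result


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_mediation_panel(
    cohort: pd.DataFrame,
    prs_z,
    mediator_specs: list[MediatorSpec],
    config: BootstrapConfig,
    outcome_col: str = "asthma",
    covariates: list[str] = MEDIATION_COVARIATES,
    rescale: bool = False,
) -> pd.DataFrame:
    """Run the bootstrap mediation analysis for a panel of biomarkers.

    Each mediator is analyzed on its own complete-case subset; BH correction
    is applied within the panel; rows are ordered by PM descending.  Each
    mediator gets an independent, reproducible bootstrap stream derived from
    the panel seed.
    """
    if not mediator_specs:
        raise PanelError("empty mediator panel")
    seeds = np.random.SeedSequence(config.seed).generate_state(len(mediator_specs))
    results = []
    errors = {}
    for spec, seed in zip(mediator_specs, seeds):
        try:
            med_z = prepare_mediator(cohort[spec.name].to_numpy(), spec)
            cfg = BootstrapConfig(n_reps=config.n_reps, seed=int(seed % (2**31)),
                                  ci_level=config.ci_level,
                                  max_refit_failures=config.max_refit_failures)
            res = bootstrap_mediation(
                cohort[outcome_col], prs_z, med_z, cohort, cfg,
                covariates=covariates, rescale=rescale,
            )
            res.mediator = spec.name
            results.append(res)
        except (DataError, DesignError, ValueError) as exc:
            logger.warning("mediator %s failed: %s", spec.name, exc)
            errors[spec.name] = str(exc)
    if not results:
        raise PanelError(f"all mediators failed: {errors}")
    padj = bh_adjust([r.p for r in results])
    for r, pa in zip(results, padj):
        r.p_adj = float(pa)
    df = pd.DataFrame([vars(r) for r in results])
    return df.sort_values("pm", ascending=False).reset_index(drop=True)
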