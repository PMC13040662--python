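"""Case-control performance evaluation of polygenic scores.

For each score the discriminative value added over clinical covariates is
quantified by fitting two logistic models — a *base* model with covariates
only (age, sex, site, genetic PCs by default) and an *expanded* model adding
the standardized PRS — and comparing their in-sample ROC AUCs (dAUC), their
Nagelkerke pseudo-R² (incremental R²), the odds ratio per SD of the score,
and odds ratios across score deciles relative to the (40, 50] percentile
bin.  Across a collection of scores, performance is related to the size of
each score's discovery GWAS by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .design import build_design
from .errors import DesignError
from .glm import LogisticFit, fit_intercept_only, fit_logistic

DEFAULT_COVARIATES = ["age", "sex", "site", "PC1", "PC2"]

DECILE_LABELS = [f"({10 * i},{10 * (i + 1)}]" for i in range(10)]
REFERENCE_DECILE = 4  # the (40,50] bin


def roc_auc(scores: np.ndarray, outcome: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic.

    (concordant pairs + 0.5 * tied pairs) / (n_case * n_control).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_ci_delong(scores, outcome, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong-type normal-approximation confidence interval.

    Uses the structural-components variance of the rank statistic:
    var = var(V10)/n1 + var(V01)/n0 with midrank placements.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    n1, n0 = pos.size, neg.size
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    allr = stats.rankdata(np.concatenate([pos, neg]))
    rpos = stats.rankdata(pos)
    rneg = stats.rankdata(neg)
    auc = (allr[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    v10 = (allr[:n1] - rpos) / n0  # placement of each case among controls
    v01 = 1.0 - (allr[n1:] - rneg) / n1
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0)
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delta_auc(base: LogisticFit, expanded: LogisticFit, outcome: np.ndarray) -> float:
    """AUC(expanded fitted probabilities) - AUC(base fitted probabilities)."""
    if base.n != expanded.n or base.n != len(outcome):
        raise ValueError("base and expanded fits must cover the same samples")
    return roc_auc(expanded.fitted, outcome) - roc_auc(base.fitted, outcome)


def nagelkerke_r2(full: LogisticFit, null: LogisticFit, tol: float = 1e-8) -> float:
    """Nagelkerke pseudo-R²: Cox-Snell rescaled to a maximum of 1.

    R²_CS = 1 - exp(-(2/n)(ll_full - ll_null));
    R²_N  = R²_CS / (1 - exp((2/n) ll_null)).
    """
    if full.n != null.n:
        raise ValueError("models must be fit to the same n")
    n = full.n
    if full.llf < null.llf - tol:
        raise ValueError("nesting violated: full model log-likelihood below null")
    llf = max(full.llf, null.llf)  # clamp tiny numerical inversions
    r2_cs = 1.0 - np.exp(-(2.0 / n) * (llf - null.llf))
    denom = 1.0 - np.exp((2.0 / n) * null.llf)
    return float(r2_cs / denom)


def incremental_nagelkerke(y, X_base, X_expanded) -> float:
    """R²_N(expanded vs intercept-only) - R²_N(base vs intercept-only)."""
    null = fit_intercept_only(y)
    base = fit_logistic(y, X_base)
    expanded = fit_logistic(y, X_expanded)
    return nagelkerke_r2(expanded, null) - nagelkerke_r2(base, null)


def decile_odds_ratios(
    prs_z: np.ndarray,
    outcome: np.ndarray,
    cohort: pd.DataFrame,
    covariates: list[str] = DEFAULT_COVARIATES,
    level: float = 0.95,
) -> pd.DataFrame:
    """Odds ratio per PRS decile relative to the (40,50] bin.

    The score is cut at its sample deciles (midpoint-interpolated quantiles,
    left-open/right-closed bins) and the outcome is regressed on the nine
    non-reference bin indicators plus covariates.  ORs are exp(coef) with
    Wald intervals; a bin without both classes is flagged non-estimable.
    """
    prs_z = np.asarray(prs_z, dtype=float)
    y = np.asarray(outcome, dtype=float)
    interior = np.quantile(prs_z, np.linspace(0.1, 0.9, 9), method="midpoint")
    # right-closed bins: value v lands in the first bin whose upper edge >= v
    bins = np.searchsorted(interior, prs_z, side="left")

    Xcov, names_cov = build_design(cohort, covariates)
    estimable = []
    dummy_cols = []
    dummy_names = []
    for b in range(10):
        in_bin = bins == b
        ok = in_bin.any() and len(np.unique(y[in_bin])) == 2
        estimable.append(bool(ok))
        if b != REFERENCE_DECILE and in_bin.any():
            dummy_cols.append(in_bin.astype(float))
            dummy_names.append(f"decile_{b}")
    X = np.column_stack([Xcov] + [c[:, None] for c in dummy_cols])
    names = names_cov + dummy_names
    fit = fit_logistic(y, X, names=names)
    zq = stats.norm.ppf(0.5 + level / 2)

    rows = []
    for b in range(10):
        n_bin = int((bins == b).sum())
        n_case = int(y[bins == b].sum())
        if b == REFERENCE_DECILE:
            rows.append((DECILE_LABELS[b], 1.0, 1.0, 1.0, n_bin, n_case, True))
            continue
        if f"decile_{b}" not in names:
            rows.append((DECILE_LABELS[b], np.nan, np.nan, np.nan, n_bin, n_case, False))
            continue
        coef = fit.coef(f"decile_{b}")
        se = fit.se(f"decile_{b}")
        ok = estimable[b] and fit.converged and np.isfinite(se)
        if ok:
            rows.append((DECILE_LABELS[b], float(np.exp(coef)),
                         float(np.exp(coef - zq * se)), float(np.exp(coef + zq * se)),
                         n_bin, n_case, True))
        else:
            rows.append((DECILE_LABELS[b], np.nan, np.nan, np.nan, n_bin, n_case, False))
    return pd.DataFrame(rows, columns=["decile", "or", "ci_low", "ci_high",
                                       "n", "n_case", "estimable"])


def performance_vs_training_n(delta_aucs, training_ns) -> tuple[float, float]:
    """Spearman correlation of per-score dAUC against discovery sample size."""
    d = np.asarray(delta_aucs, dtype=float)
    n = np.asarray(training_ns, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 scores")
    if np.unique(d).size == 1 or np.unique(n).size == 1:
        raise ValueError("constant ranks: Spearman correlation undefined")
    res = stats.spearmanr(d, n)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PerformanceReport:
    """Per-score discrimination summary (base vs expanded logistic models)."""

    score_id: str
    n: int
    auc_base: float
    auc_base_ci: tuple
    auc_expanded: float
    auc_expanded_ci: tuple
    delta_auc: float
    incremental_nagelkerke_r2: float
    or_per_sd: float
    or_per_sd_ci: tuple
    or_per_sd_p: float
    decile_ors: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decile_ors"] = self.decile_ors.to_dict(orient="records")
        return d


def evaluate_prs(
    cohort: pd.DataFrame,
    prs_z: np.ndarray,
    outcome_col: str = "asthma",
    covariates: list[str] = DEFAULT_COVARIATES,
    score_id: str = "PRS",
) -> PerformanceReport:
    """Full performance evaluation of one standardized score.

    Rows with missing outcome or covariates are dropped (listwise) before
    fitting; the PRS must align row-wise with the cohort table.
    """
    df = cohort.reset_index(drop=True).copy()
    df["_prs_z"] = np.asarray(prs_z, dtype=float)
    needed = [outcome_col, "_prs_z"] + covariates
    cc = df.dropna(subset=needed)
    y = cc[outcome_col].to_numpy(dtype=float)

    X_base, names_base = build_design(cc, covariates)
    X_exp = np.column_stack([X_base, cc["_prs_z"].to_numpy()])
    names_exp = names_base + ["prs_z"]
    base = fit_logistic(y, X_base, names=names_base)
    expanded = fit_logistic(y, X_exp, names=names_exp)
    if not (base.converged and expanded.converged):
        raise DesignError("base or expanded logistic model did not converge")

    auc_b, lo_b, hi_b = auc_ci_delong(base.fitted, y)
    auc_e, lo_e, hi_e = auc_ci_delong(expanded.fitted, y)
    inc_r2 = incremental_nagelkerke(y, X_base, X_exp)

    coef = expanded.coef("prs_z")
    se = expanded.se("prs_z")
    zq = stats.norm.ppf(0.975)
    pval = 2 * stats.norm.sf(abs(coef / se))
    deciles = decile_odds_ratios(cc["_prs_z"].to_numpy(), y, cc, covariates)

    return PerformanceReport(
        score_id=score_id,
        n=len(cc),
        auc_base=auc_b,
        auc_base_ci=(lo_b, hi_b),
        auc_expanded=auc_e,
        auc_expanded_ci=(lo_e, hi_e),
        delta_auc=auc_e - auc_b,
        incremental_nagelkerke_r2=inc_r2,
        or_per_sd=float(np.exp(coef)),
        or_per_sd_ci=(float(np.exp(coef - zq * se)), float(np.exp(coef + zq * se))),
        or_per_sd_p=float(pval),
        decile_ors=deciles,
    )
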