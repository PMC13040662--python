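"""Synthetic case-control cohort generator with known mediation structure.

The generator produces every input the downstream pipeline consumes —
genotype dosages, a scoring file, a phenotype/covariate table with
biomarkers, and expression module scores — from an explicit structural
model, so that each stage can be validated against ground truth:

* genotypes: independent Hardy-Weinberg variants, dosage ~ Binomial(2, af);
* PRS: weighted sum of effect-allele dosages with zero-centered weights;
* mediators: latent log-scale value m = a * PRS_z + covariate terms + N(0,1),
  exposed as a log-normal biomarker exp(mu + sigma * m) with optional
  lower detection-limit censoring flags;
* outcome: Bernoulli(logit^-1(intercept + c' * PRS_z + sum_k b_k * z(m_k)
  + covariate terms));
* module scores: a_module * PRS_z + technical (batch/RIN/GC) effects + noise.

The theoretical percent mediation on the latent log-odds scale is
a*b / (a*b + c'), recorded per mediator as ground truth.  All randomness
derives from a single seed; identical parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import HarmonizationError, ParameterError
from .genotypes import GenotypeMatrix
from .scoring import ScoringFile, REQUIRED_COLUMNS

SITES = [f"S{i}" for i in range(1, 8)]
BATCHES = [f"B{i}" for i in range(1, 5)]

# non-complementary allele pairs, so simulated variants are never
# strand-ambiguous (ambiguity handling is exercised with hand fixtures)
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"),
                 ("C", "A"), ("G", "A"), ("T", "C"), ("T", "G")]


@dataclass
class BiomarkerParams:
    """One log-normal biomarker mediator.

    log_mean/log_sd place the marker on its assay scale (kU/L, PAU/L,
    cells/mm^3); a_path and b_path are the latent mediation effects;
    detection_limit triggers censoring flags below the limit.
    """

    name: str
    log_mean: float = 0.0
    log_sd: float = 1.0
    a_path: float = 0.0
    b_path: float = 0.0
    detection_limit: float | None = None
    offset: float = 0.0
    missing_rate: float = 0.0


def default_biomarkers() -> list[BiomarkerParams]:
    """Four-marker panel shaped like a T2-inflammation biomarker set:
    total IgE, multi-allergen specific IgE, eosinophils, neutrophils."""
    return [
        BiomarkerParams("tige", log_mean=4.0, log_sd=1.5, a_path=0.25,
                        b_path=0.5, detection_limit=2.0, missing_rate=0.005),
        BiomarkerParams("sige", log_mean=-0.1, log_sd=2.3, a_path=0.25,
                        b_path=0.5, detection_limit=0.1, missing_rate=0.006),
        BiomarkerParams("eos", log_mean=4.8, log_sd=1.0, a_path=0.10,
                        b_path=0.3, offset=1.0, missing_rate=0.04),
        BiomarkerParams("neut", log_mean=7.9, log_sd=0.55, a_path=0.05,
                        b_path=0.05, offset=1.0, missing_rate=0.05),
    ]


def default_covariate_effects() -> dict:
    """Small non-null covariate effects (on standardized age, female
    indicator, and PCs) so adjustment is actually doing work."""
    return {
        "mediator": {"age": 0.10, "female": 0.10, "PC1": 0.05, "PC2": -0.05},
        "outcome": {"age": 0.10, "female": -0.20, "PC1": 0.10, "PC2": -0.10},
    }


@dataclass
class SimulationParams:
    """Everything the generator needs; see module docstring for the model."""

    n_samples: int = 673
    n_variants: int = 500
    allele_freqs: np.ndarray | None = None  # drawn U(0.05, 0.95) if None
    weight_sd: float = 0.05
    biomarkers: list[BiomarkerParams] = field(default_factory=default_biomarkers)
    c_prime: float = 0.3
    intercept: float = 0.0
    covariate_effects: dict = field(default_factory=default_covariate_effects)
    casi_positive_fraction: float = 0.7
    n_pcs: int = 2
    n_modules: int = 24
    module_a: np.ndarray | None = None  # per-module PRS effect; default 0s
    module_noise_sd: float = 1.0
    batch_effect_sd: float = 0.3
    rin_coef: float = 0.1
    gc_coef: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ParameterError("n_samples must be >= 2")
        if self.allele_freqs is not None:
            af = np.asarray(self.allele_freqs, dtype=float)
            if len(af) != self.n_variants:
                raise ParameterError("allele_freqs length must equal n_variants")
            if np.any(af <= 0) or np.any(af >= 1):
                raise ParameterError("allele frequencies must be strictly in (0,1)")
            self.allele_freqs = af
        for bm in self.biomarkers:
            if not 0 <= bm.missing_rate <= 1:
                raise ParameterError(f"{bm.name}: missing_rate must be in [0,1]")
        if self.module_a is not None and len(self.module_a) != self.n_modules:
            raise ParameterError("module_a length must equal n_modules")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for recovery tests."""

    true_prs: np.ndarray            # raw weighted-sum score per sample
    prs_z: np.ndarray
    true_pm: dict                   # mediator name -> a*b/(a*b + c')
    latent_mediators: pd.DataFrame  # per-sample latent values before censoring
    prevalence: float = np.nan


def _rng(params: SimulationParams, stage: int) -> np.random.Generator:
    """Independent, reproducible stream per pipeline stage from one seed."""
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(stage,)))


def simulate_genotypes(params: SimulationParams) -> GenotypeMatrix:
    """Independent HWE variants on one pseudo-chromosome: d ~ Binomial(2, af).

    Metadata carries the generating allele frequency as the reference AF of
    the alt allele.
    """
    rng = _rng(params, 0)
    m = params.n_variants
    af = params.allele_freqs
    if af is None:
        af = rng.uniform(0.05, 0.95, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = pd.DataFrame({
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "ref": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "alt": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "af": af,
    })
    n = params.n_samples
    dosages = rng.binomial(2, af, size=(n, m)).astype(float)
    sample_ids = [f"SAMP{i:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)


def simulate_scoring_file(genotypes: GenotypeMatrix, params: SimulationParams) -> ScoringFile:
    """One weight per genotyped variant, w ~ N(0, weight_sd); the effect
    allele is the ref or alt allele with equal probability."""
    rng = _rng(params, 1)
    m = genotypes.n_variants
    weights = (rng.normal(0.0, params.weight_sd, size=m)
               if params.weight_sd > 0 else np.zeros(m))
    effect_is_alt = rng.random(m) < 0.5
    gv = genotypes.variants
    df = pd.DataFrame({
        "chr_name": gv["chrom"].astype(str),
        "chr_position": gv["pos"].astype(int),
        "effect_allele": np.where(effect_is_alt, gv["alt"], gv["ref"]),
        "other_allele": np.where(effect_is_alt, gv["ref"], gv["alt"]),
        "effect_weight": weights,
    })[REQUIRED_COLUMNS]
    return ScoringFile(score_id=f"SIM{params.seed:06d}", variants=df)


def _true_raw_prs(genotypes: GenotypeMatrix, scoring: ScoringFile) -> np.ndarray:
    """Ground-truth weighted sum of effect-allele dosages (plain dot
    product, independent of the harmonization code path)."""
    geno_keys = {
        (str(r.chrom), int(r.pos)): (j, r.ref, r.alt)
        for j, r in enumerate(genotypes.variants.itertuples(index=False))
    }
    raw = np.zeros(genotypes.n_samples)
    for r in scoring.variants.itertuples(index=False):
        key = (str(r.chr_name), int(r.chr_position))
        if key not in geno_keys:
            raise HarmonizationError(
                f"scoring variant {key} absent from genotypes"
            )
        j, ref, alt = geno_keys[key]
        d = genotypes.dosages[:, j]
        if r.effect_allele == alt:
            raw += r.effect_weight * d
        elif r.effect_allele == ref:
            raw += r.effect_weight * (2.0 - d)
        else:
            raise HarmonizationError(
                f"scoring alleles at {key} incompatible with genotypes"
            )
    return raw


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def theoretical_pm(a: float, b: float, c_prime: float) -> float:
    """Product/total decomposition on the latent log-odds scale."""
    if b == 0:
        return 0.0
    ab = a * b
    total = ab + c_prime
    if total == 0:
        return np.nan
    return ab / total


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    scoring: ScoringFile,
    params: SimulationParams,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Covariates, biomarkers with a-path structure, and the binary outcome.

    Returns the cohort table (one row per sample) and the recorded ground
    truth.  The severity indicator CASI >= 1 is assigned to
    ``casi_positive_fraction`` of cases; controls have no CASI.
    """
    rng = _rng(params, 2)
    n = genotypes.n_samples
    raw = _true_raw_prs(genotypes, scoring)
    prs_z = _zscore(raw) if raw.std(ddof=1) > 0 else np.zeros(n)

    age = rng.uniform(8, 89, size=n)
    female = rng.random(n) < 0.6
    site = rng.choice(SITES, size=n)
    pcs = rng.normal(size=(n, params.n_pcs))

    cov_vals = {"age": _zscore(age), "female": female.astype(float)}
    for k in range(params.n_pcs):
        cov_vals[f"PC{k + 1}"] = pcs[:, k]

    def cov_term(effects: dict) -> np.ndarray:
        out = np.zeros(n)
        for name, coef in effects.items():
            if name in cov_vals:
                out = out + coef * cov_vals[name]
        return out

    med_cov = cov_term(params.covariate_effects.get("mediator", {}))
    out_cov = cov_term(params.covariate_effects.get("outcome", {}))

    cohort = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "age": age,
        "sex": np.where(female, "F", "M"),
        "site": site,
    })
    for k in range(params.n_pcs):
        cohort[f"PC{k + 1}"] = pcs[:, k]

    latent = {}
    logit = np.full(n, params.intercept, dtype=float) + params.c_prime * prs_z + out_cov
    truth_pm = {}
    for bm in params.biomarkers:
        m_lat = bm.a_path * prs_z + med_cov + rng.normal(size=n)
        latent[bm.name] = m_lat
        logit = logit + bm.b_path * _zscore(m_lat)
        truth_pm[bm.name] = theoretical_pm(bm.a_path, bm.b_path, params.c_prime)
        value = np.exp(bm.log_mean + bm.log_sd * m_lat)
        below = (value < bm.detection_limit) if bm.detection_limit else np.zeros(n, bool)
        cohort[bm.name] = value
        cohort[f"{bm.name}_below_limit"] = below

    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    cohort["asthma"] = y

    casi = np.full(n, np.nan)
    is_case = y == 1
    pos = rng.random(n) < params.casi_positive_fraction
    casi[is_case] = np.where(pos[is_case], 1 + rng.poisson(3, size=n)[is_case], 0)
    cohort["casi"] = casi

    for bm in params.biomarkers:
        cohort[f"{bm.name}_below_limit"] = cohort[f"{bm.name}_below_limit"].astype("boolean")
        if bm.missing_rate > 0:
            miss = rng.random(n) < bm.missing_rate
            cohort.loc[miss, bm.name] = np.nan
            cohort.loc[miss, f"{bm.name}_below_limit"] = pd.NA

    truth = SyntheticTruth(
        true_prs=raw,
        prs_z=prs_z,
        true_pm=truth_pm,
        latent_mediators=pd.DataFrame(latent),
        prevalence=float(y.mean()),
    )
    return cohort, truth


def simulate_module_scores(
    cohort: pd.DataFrame,
    truth: SyntheticTruth,
    params: SimulationParams,
) -> pd.DataFrame:
    """Append expression-module scores and technical covariates.

    module_k = a_k * PRS_z + batch effect + rin_coef*(RIN-7) + gc_coef*(GC-0.5)
    + N(0, module_noise_sd).  Batch is categorical, RIN ~ N(7,1) clipped to
    [2,10], GC ~ N(0.5, 0.02).
    """
    rng = _rng(params, 3)
    n = len(cohort)
    prs_z = truth.prs_z
    a = (np.asarray(params.module_a, dtype=float)
         if params.module_a is not None else np.zeros(params.n_modules))

    out = cohort.copy()
    batch_levels = rng.integers(0, len(BATCHES), size=n)
    batch_shift = rng.normal(0, params.batch_effect_sd, size=len(BATCHES))
    out["batch"] = [BATCHES[i] for i in batch_levels]
    out["RIN"] = np.clip(rng.normal(7, 1, size=n), 2, 10)
    out["GC"] = rng.normal(0.5, 0.02, size=n)

    tech = (batch_shift[batch_levels]
            + params.rin_coef * (out["RIN"].to_numpy() - 7.0)
            + params.gc_coef * (out["GC"].to_numpy() - 0.5))
    for k in range(params.n_modules):
        out[f"M{k + 1}"] = (a[k] * prs_z + tech
                            + rng.normal(0, params.module_noise_sd, size=n))
    return out


def simulate_cohort(params: SimulationParams):
    """Convenience wrapper: genotypes -> scoring file -> phenotypes -> modules.

    Returns (genotypes, scoring, cohort, truth) with module scores and
    technical covariates already merged into the cohort table.
    """
    genotypes = simulate_genotypes(params)
    scoring = simulate_scoring_file(genotypes, params)
    cohort, truth = simulate_phenotypes(genotypes, scoring, params)
    cohort = simulate_module_scores(cohort, truth, params)
    return genotypes, scoring, cohort, truth
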