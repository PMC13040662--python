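# Methods

## Scope and model

`prsmed` implements a case–control analysis pipeline for polygenic risk
scores (PRS) of asthma: scoring and harmonization of PGS-Catalog-style
weight files against genotype dosages, covariate-adjusted performance
evaluation, and a three-regression percent-mediation analysis of the
PRS–asthma relationship through clinical biomarkers and nasal-epithelium
expression-module scores. A synthetic-cohort generator provides ground
truth for every stage.

### PRS scoring

A score is `raw_i = Σ_j w_j d'_ij` over harmonized variants, where `d'` is
the effect-allele dosage after flip resolution (`2 − d` when the effect
allele is the genotype reference allele). Harmonization keys variants by
(chromosome, 1-based position, unordered allele pair); rsIDs are ignored.
Exclusions, applied in this order per scoring row: non-autosomal;
duplicated scoring position (all copies dropped); strand-ambiguous allele
pair (A/T, C/G — excluded unconditionally, no frequency-based rescue);
genotype position multi-allelic. Variants absent from the genotypes (or
present with incompatible alleles) are backfilled with `2 × af` of the
effect allele from a reference allele-frequency table; sample-level missing
dosages at matched variants use the genotype metadata AF the same way.
`match_rate = n_matched / n_total` — backfilled variants count against the
match rate but still contribute to scores that pass the gate, which is
strict (`> 0.75` by default; a rate of exactly 0.75 fails). Raw scores are
Z-standardized (n−1 denominator) before any modelling.

### Performance evaluation

Logistic regression is fit by Newton–Raphson IRLS (convergence when the
max absolute coefficient change < 1e-8, at most 100 iterations; separation
is reported via a `converged` flag, never silently). The base model is
outcome ~ age + sex + site + PC1 + PC2 (categoricals reference-coded,
alphabetical first level); the expanded model adds the standardized PRS.
AUC is the Mann–Whitney rank statistic on in-sample fitted probabilities —
optimism is acknowledged, not corrected — with DeLong structural-component
confidence intervals. ΔAUC = AUC_expanded − AUC_base. Incremental
Nagelkerke R² is `R²_N(expanded vs intercept-only) − R²_N(base vs
intercept-only)` with `R²_N = R²_CS / (1 − exp((2/n)·ll_null))`. Decile odds
ratios cut the standardized PRS at sample deciles (midpoint-interpolated
quantiles, left-open/right-closed bins) with the (40,50] bin as reference;
ORs are `exp(coef)` with Wald 95% intervals; empty or single-class bins are
flagged non-estimable rather than dropped. Across scores, ΔAUC is related
to discovery-GWAS sample size by Spearman rank correlation.

### Mediation

For a standardized mediator M and standardized PRS:

    a  : M ~ PRS + covariates          (linear)
    c  : Y ~ PRS + covariates          (logistic)
    c' : Y ~ PRS + M + covariates      (logistic)

Percent mediation is `PM = (c − c') / c` on the log-odds scale, the
difference-in-coefficients form, fit on one listwise-deleted complete-case
sample per mediator (so each biomarker keeps its own n). PM is not
truncated to [0, 1]; negative values are reportable. Inference is a
nonparametric bootstrap resampling whole rows (unstratified) with PM
recomputed per resample: the 95% CI is the (2.5, 97.5) percentile pair and
the two-sided p-value is `2·min(#{PM* ≤ 0}, #{PM* ≥ 0})/B`, floored at
`1/B` (default B = 10,000). Resamples with undefined PM (|c| < 1e-10) or
non-convergent fits are excluded and counted; the run aborts if they exceed
a configurable fraction. BH correction is applied within a panel; the
biomarker and expression-module panels are separate families.

Biomarker preparation: left-censored assay values below the detection
limit (tIgE < 2.00 kU/L, phadiatop sIgE < 0.1 PAU/L) are set to half the
limit; cell counts receive a +1 offset; everything is natural-log
transformed and Z-scored over non-missing entries. Atopy is tIgE > 100
kU/L (strict) and/or sIgE ≥ 0.36 PAU/L (inclusive); a sample missing one
marker is classified from the other, missing both propagates.

Expression modules are generic continuous per-sample summaries
(eigengene-like); module–PRS association adjusts for age, sex, library
batch, site, RIN, GC content and PC1–2, while module mediation uses the
clinical covariate set (age, sex, site, PC1–2), each exposed as a
configurable preset. Module mediation runs on the current-asthma subset
(controls plus cases with CASI ≥ 1) and module scores are re-standardized
within that subset.

PM here is a statistical decomposition. With a binary outcome the
difference-in-coefficients estimator inherits logistic non-collapsibility:
conditioning on a mediator that strongly predicts the outcome rescales
`c'` even when the mediator is independent of the PRS, biasing PM away
from 0 (roughly by the factor relating the two models' latent scales). An
optional MacKinnon–Dwyer rescaling flag (`rescale=True`) divides c and c'
by the SD of each model's linear predictor to mitigate this; the default is
off. Consequently recovery and calibration experiments are restricted to
regimes where the bias is small: prevalence near 0.5, |effects| ≤ 1, and a
b = 0 arm for the PM = 0 null (an a = 0, large-b arm is *not* centered at
PM = 0 for this estimator).

## Synthetic cohort

The generator is the package's ground-truth instrument, not a data set:
it emulates the statistical structure the analysis assumes, with defaults
chosen to resemble a 673-sample African-ancestry asthma case–control study.

* Genotypes: independent HWE variants, `d ~ Binomial(2, af)`, af drawn
  U(0.05, 0.95) unless supplied; one pseudo-chromosome; simulated allele
  pairs are never strand-ambiguous (ambiguity handling is tested with hand
  fixtures). No LD, admixture, or imputation-quality structure.
* Scoring file: `w ~ N(0, 0.05)`; effect allele is ref or alt with equal
  probability, exercising flip resolution.
* Covariates: age ~ U(8, 89); sex female with probability 0.6; 7 sites;
  PCs ~ N(0,1). Covariate effects on mediator and outcome default to small
  non-zero values so adjustment matters.
* Mediators: latent `m = a·PRS_z + covariate terms + N(0,1)` (standard
  normal noise on the log scale), biomarker `exp(μ + σ·m)` — so the
  pipeline's log transform recovers linearity. Defaults echo the assay
  scales (geometric means ≈ 54 kU/L tIgE, 0.9 PAU/L sIgE, 130 eos,
  2700 neut) with detection limits 2.0 and 0.1 and per-column missingness
  0.5–5%. Default paths a/b = (0.25, 0.5), (0.25, 0.5), (0.1, 0.3),
  (0.05, 0.05) with c' = 0.3 reproduce the qualitative ordering
  tIgE ≈ sIgE > eosinophils > neutrophils.
* Outcome: `Y ~ Bernoulli(logit⁻¹(intercept + c'·PRS_z + Σ b_k·z(m_k) +
  covariate terms))`, intercept 0 (prevalence ≈ 0.5). The severity
  indicator CASI ≥ 1 is assigned to 70% of cases (the full severity index
  is not modelled); controls carry no CASI.
* Modules: `M_k = a_k·PRS_z + batch shift + 0.1·(RIN−7) + 1.0·(GC−0.5) +
  N(0,1)`, with categorical batch (4 levels), RIN ~ N(7,1) clipped to
  [2,10], GC ~ N(0.5, 0.02); 24 modules by default, a_k = 0 unless planted.

Ground truth records the raw weighted-sum PRS (computed by a plain dot
product, deliberately independent of the harmonization code path), the
latent mediators, and the theoretical `PM = a·b/(a·b + c')` per mediator
(1 exactly under full mediation c' = 0, 0 exactly when b = 0).

All randomness flows from one seed through per-stage `SeedSequence`
spawns: identical parameters and seed give bit-identical output, and each
stage is individually reproducible.

What passing tests do **not** show about real data: no LD or fine-scale
population structure, no genotype-imputation error, independent variants
only, log-normal biomarkers with exactly standard-normal latent noise, and
missingness completely at random.

## Numerical choices

* IRLS: |linear predictor| clipped at 35; likelihood clipped at 1e-12;
  coefficients beyond 1e3 in absolute value mark separation; bootstrap
  refits warm-start from the full-data coefficients.
* Nagelkerke: tiny negative improvements (within 1e-8) are clamped to 0;
  larger nesting violations raise.
* Quantile bin edges use midpoint interpolation; assignment is
  right-closed via binary search, so tied edges yield empty (flagged)
  bins instead of errors.
* Bootstrap seeds for panel members derive from one `SeedSequence`, so a
  panel is reproducible and mediators are independently resampled.
* Underflowed association p-values are clamped to the smallest positive
  float before BH (whose domain is (0, 1]).

## Problem sizes

Default verification runs use n = 673–5000 samples, 50–500 variants,
B = 100–1000 bootstrap replicates in tests (B = 10,000 remains the
analysis default), 100 replicates for recovery and 500 for null
calibration. The acceptance script runs the study-scale pipeline (n = 673,
B = 1000) and one recovery scenario (n = 5000, B = 1000).

## Known limitations

* In-sample AUC is optimistic; no cross-validation is offered.
* Percent mediation is reported without causal interpretation: reverse
  causation, unmeasured confounding, and pleiotropy are indistinguishable
  in this design.
* The difference-in-coefficients PM is non-collapsibility-biased for
  strong mediators of binary outcomes (see above); the rescaling flag only
  mitigates this.
* Harmonization does no liftover, strand-flip repair via reference, or
  indel normalization; multi-allelic sites are excluded, not decomposed.
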