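# Methods

## Problem and model

`casemix` implements a concurrent (retrospective) case-mix system for mental
health care: annual per-patient cost, as a proxy for disease burden, is
modelled from age, sex and diagnoses alone.  Diagnoses enter as indicators
for *expanded groups* — subdivisions of CCSR-style diagnostic categories
obtained by recursively splitting on successive characters of the normalized
ICD-10-CM code until a group's distinct-patient count falls to a threshold
T or the fourth character is reached.  Cost is heavily right-skewed, so four
model families are compared on a development/validation split:

* OLS on raw dollars;
* Gamma GLM with log link (IRLS; for the log link the working weights are
  identically 1, so each iteration is an OLS solve on the working response);
* log-linear (OLS on ln y);
* Box–Cox: OLS on z = (y^λ − 1)/λ, with λ chosen by grid search.

For the transformed-outcome families, raw-dollar predictions use Duan's
nonparametric smearing estimator: ŷ(x) = (1/n_dev) Σ_i g⁻¹(x'β + e_i) over
the development residuals e_i, which corrects retransformation bias without
a normality assumption.  Fit is reported on both scales with R², adjusted
R², PVE, MAPE (as a ratio) and MAE.  PVE is the absolute-deviation analogue
1 − Σ|y−ŷ|/Σ|y−ȳ|; under heavy tails it is far less dominated by extreme
patients than R² and is the more honest ranking metric.  R² is always the
1 − SSE/SST form about the evaluation-sample mean, never a squared
correlation.

## Synthetic cohort generator

No patient-level data are shipped; the generator emulates the published
summary structure of a very large integrated-health-system mental-health
cohort: strictly positive costs with mean more than double the median,
~18% female, ages 20–95, diagnostic categories of very unequal prevalence
(log-spaced 50%→1% across 12 desk-scale categories), and comorbidity
(zero-truncated Poisson number of categories, mean 2.5, sampled without
replacement by prevalence weight via Gumbel top-k).

Costs are generated by the Box–Cox model run forward:
z = β₀ + β_age(age−50)/10 + β_female·1[female] + Σ_g β_g·1[g] + ε,
ε ~ N(0, σ²), cost = (λz+1)^{1/λ} clamped below at a $25 floor.  Default
calibration (λ=0.5, β₀=112, σ=75, scalar β_group=65 spread over categories
as a −0.9×…2.4× ramp anti-aligned with prevalence — common conditions mild,
rare ones severe) was chosen once to land near the published profile:
median ≈ $2k, mean/median ≈ 2.3, transformed-scale R² ≈ 0.44.  A
coefficient of variation of 3 (the published cohort's SD/mean) is not
attainable from an inverse-Box–Cox(λ=0.5) Gaussian, whose CV is bounded by
√2 before clamping; the generator reproduces the skew *direction and
ordering phenomena* (PVE ≪ R², log-linear collapse on retransformation),
not the full tail weight of real claims data.

About 20% of default-spec draws fall below the transform's domain
(λz+1 ≤ 0) and are clamped to the floor.  That point mass is a deliberate,
realistic misspecification: it biases λ-recovery downward.
`synthetic.spec_for_lambda` therefore provides a *well-specified* variant
(all transformed-scale parameters rescaled to the target λ's scale, effect
spread ×0.35, σ=25 on the λ=0.5 scale, < 1% clamped) which is what
parameter-recovery experiments use; the default spec is what the
study-emulation experiments use.  Real data differ from both: utilization
is not generated, costs have no encounter-level structure, and code
assignment within a category is uniform — so passing tests show internal
correctness and qualitative fidelity, not external validity.

## Grouper conventions

"Digit" positions are successive characters of the normalized code
(uppercase, dot removed), so depth 1 is the ICD-10 letter and depth 4 the
fourth character.  Distinct patients (not code occurrences) are counted per
node.  A node whose codes all share the next character collapses through a
single-child chain; a node that still exceeds T at depth 4 stops there
(forced leaf).  Codes shorter than the current split position form terminal
exact-match buckets; these can violate the "count ≤ T unless at max depth"
property for mixed-length real codes (never for the fixed-length synthetic
universe) and are flagged `terminal` in the output.  The threshold is
configurable as an absolute count (the full-scale study's 6000) or a cohort
fraction (default 0.3%, floor 1), which scales the procedure to desk-size
cohorts.  Groups are emitted in category-id then prefix order, so output is
deterministic.

Hierarchy imposition keeps, per patient and category, the group with the
highest rank; the default ranking is descending development-sample mean
cost, a stand-in for clinical severity orderings.  On default synthetic
cohorts each patient carries at most one code per category, so imposition
is a no-op there; it binds when patients carry multiple codes of one
category (covered by dedicated unit fixtures).

## Design matrix

Intercept; age centered at 50 (years); age-stratum indicators <35, 35–44,
45–54, 55–64, 65–74, ≥75 with 45–54 (mid-distribution) as the default
reference; a female indicator; one indicator per expanded group.  Both the
linear age term and the strata are retained — the reference stratum absorbs
the collinearity.  Constant columns are dropped with a logged warning
rather than raising, because small cohorts routinely lack a stratum.

## Numerical choices

* All linear fits are exact QR solves with an explicit rank check; no
  stochastic optimizers, so every fit is deterministic.
* λ grid: 0 to 1 in steps of 0.02; selection by validation-sample raw-scale
  R² by default (validation PVE and the classical profile likelihood are
  alternatives); ties go to the smaller λ.
* During the λ grid search the smearing set is compressed to 512 empirical
  quantiles (midpoint grid) per candidate — accurate to well under 1%
  relative on the means involved — and the returned fit carries the full
  residual vector, which final predictions use.
* Smearing domain violations (λz+1 ≤ 0) are clamped to 1e−6 and counted on
  the fit (`clamp_count`); silent failure would be worse than a logged clamp.
* Gamma IRLS converges on relative deviance change < 1e−10; dispersion is
  Pearson-profiled after convergence and affects nothing downstream.
* Stepwise selection is classical partial-F at α_entry = α_stay = 0.05,
  ties broken by column order; at study-like n selection is immaterial, so
  it is off by default in the harness.
* The development/validation overfitting gap is measured on each model's
  *estimation* scale (raw for OLS, transformed for log-linear/Box–Cox,
  deviance pseudo-R² for Gamma): raw-scale R² of a retransformed model is
  dominated by a few extreme patients and is not a stable overfitting
  diagnostic.

## Problem sizes

Desk-scale defaults: 20,000 patients, 12 categories × 9 codes, ~108
expanded groups (T = 60 at the 0.3% fraction).  Parameter-recovery and
smearing-bias experiments use n = 50,000–100,000.  These sizes were chosen
so the full analysis reruns from scratch in minutes on one core while
keeping Monte-Carlo error inside the tolerances asserted by the tests.

## Known limitations

* The exact published PVE formula is cited, not printed, in the source
  literature; the absolute-deviation analogue used here matches the
  qualitative published pattern (PVE ≪ R² under heavy tails) but is a
  documented choice (`metrics.pve`).
* The published Gamma column reports NA for R²/PVE; this package computes
  them (they are needed to rank models) and flags only the transformed
  scale as not applicable.
* Single pooled Duan estimator only; no subgroup-specific smearing under
  heteroscedasticity.
* No two-part (hurdle) models, no cost outcomes of zero, no socioeconomic
  covariates (deliberately, to match standard case-mix inputs).
* CatBoost is benchmarked only when installed; the adapter registry skips
  missing libraries with a logged notice.
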