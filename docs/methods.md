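# Methods

## Estimand and estimator

The target is the causal effect of serum 25-hydroxyvitamin D (25(OH)D, in
nmol/L, VDSP-standardized) on the all-cause mortality hazard, expressed as a
hazard ratio per k nmol/L *decrease* (k = 20 by default). Identification is
by instrumental variables: an unweighted allele-count score G over vitamin D
synthesis-pathway SNPs is (i) associated with 25(OH)D, (ii) randomly
assorted and hence independent of behavioural confounders, and (iii)
assumed to affect mortality only through 25(OH)D (no pleiotropy; transport-
and catabolism-pathway genes are deliberately excluded from the scores).

Estimation is two-stage on one sample:

1. **Stage 1 (G → X).** OLS of 25(OH)D on the score, adjusted for study,
   age, sex, season of blood draw, BMI, smoking, diabetes, hypertension,
   CVD history and cancer history. The score coefficient is β_GX (nmol/L
   per counted allele; negative under the lowering-allele orientation).
   Instrument strength is summarized by the squared t-statistic of the
   score term (its single-degree F) and the partial R² = t²/(t² + df_resid).
2. **Stage 2 (G → Y).** Cox proportional hazards of death on the score with
   the same adjustment set; β_GY is the per-allele log-hazard. Ties are
   handled by Efron's method (lifelines' default): with follow-up recorded
   at coarse resolution ties are common and Breslow's approximation is more
   biased.
3. **Wald ratio.** HR(k) = exp(k·β_GY/|β_GX|). The magnitude |β_GX| is used
   together with the convention that counted alleles lower the exposure, so
   a positive per-allele hazard yields HR > 1 per decrease. SE of the ratio
   by the first-order delta method,
   SE² = SE(β_GY)²/β_GX² + β_GY²·SE(β_GX)²/β_GX⁴, and 95% CI
   exp(k·ratio ± 1.96·k·SE). A Fieller interval (quadratic inversion,
   possibly unbounded) is available as an option but is not the default:
   the reported intervals are symmetric on the log scale, which only the
   delta method produces. A first-stage F < 10 flags the result as
   weak-instrument; no weak-instrument-robust inference is attempted.

All 95% intervals use z = 1.96. Exposure values are restricted to
0–150 nmol/L (closed at 150: the top category is printed "100–150") before
modelling; the excluded person and death counts are always reported.

## Secondary analyses

* **Observational scale.** Cox on −X/20 so exp(β) reads per 20 nmol/L
  decrease, and on six exposure categories (<30, 30–39.9, 40–49.9, 50–74.9,
  75–99.9 reference, 100–150 nmol/L). Printed ".9" bounds are display
  artifacts of 0.1 precision, so bins are implemented half-open
  [lower, next) with the last closed at 150.
* **Midpoint projections.** A per-nmol/L (decrease) log-HR β is projected
  onto category c as HR_c = exp((median_ref − median_c)·β) using observed
  per-category medians; the reference projects to exactly 1, and CI bounds
  are carried through the same linear map.
* **Rate shapes.** Deaths as Poisson counts with person-years exposure;
  mean rate linear (identity link, fitted by constrained maximum likelihood
  with rates floored at 1e-10), log-linear (log link), and a natural cubic
  spline with 4 df on the log scale (display only). Linear vs log-linear
  are non-nested and the comparison test is not standardized, so the
  package reports the AIC difference plus a parametric-bootstrap p-value
  (data re-simulated under the fitted linear model; tail probability of the
  observed log-likelihood advantage of the log-linear fit) and flags the
  bootstrap as a stand-in in its output.
* **Diagnostics.** Balance: each of ten measured confounders (the nine
  non-study adjustment covariates plus systolic blood pressure) tested per
  cohort against each score at the Bonferroni level 0.05/(3·10) = 0.0017 —
  OLS slope t-test for continuous variables, logistic Wald for binary,
  OLS F across dummies for season. The score is the predictor, matching
  the question "is the instrument associated with the confounder". Sex
  effect-modification: refit of the G→X, X→Y or G→Y model with a
  sex-by-predictor product term, Wald p-value.

## The synthetic cohort generator

`SimConfig` emulates the pooled three-cohort sample (AGES n=3172, LURIC
n=2864, Tromsø n=4465; N=10,501). Per cohort, covariates are drawn from the
published marginal summaries (age, BMI, SBP normal; sex and comorbidities
Bernoulli; blood-draw month uniform, mapped to season: spring = Mar–May,
summer = Jun–Aug, fall = Sep–Nov, winter = Dec–Feb). Genotypes are
Hardy–Weinberg Binomial(2, p) draws, p = 0.4 per SNP by default (the
counted-allele frequencies are not published; 0.4 is a typical common-variant
frequency and is configurable).

Exposure: X = cohort mean + β·(allele sum − expectation) + confounder terms
+ N(0, 18 nmol/L), floored at 0.5 nmol/L; β = −1.33 nmol/L per counted
allele by default, the residual SD matching the published pooled SD of
~18 nmol/L. An optional sinusoidal seasonal term (default amplitude 0)
peaks in late summer.

Survival: log-hazard = log(h₀) + γ·(51.7 − X) + confounder terms, with
γ = log(1.20)/20 per nmol/L decrease (the published observational per-20
hazard ratio serves as the default causal truth) and h₀ = 0.027/person-year
at the pooled covariate means, calibrated so that ~38% of participants die
before the administrative censoring horizon of 15 years, matching the
pooled death fraction. Event times are exponential given the linear
predictor (the Cox analysis is baseline-agnostic); a Weibull shape
parameter is exposed for sensitivity work. Default confounder coefficients
give classical confounding: age, male sex, smoking, diabetes, hypertension,
CVD and cancer history raise the hazard and (except age and sex, mildly)
depress 25(OH)D; SBP is generated as a pure balance variable with no
effects.

A single root seed drives `numpy` `SeedSequence` substreams, one per
cohort, so runs are exactly reproducible and resizing one cohort does not
perturb the others.

What the generator does **not** emulate: joint covariate correlations
(only marginals are published, so covariates are independent within
cohort), linkage disequilibrium, population stratification, staggered
entry/loss to follow-up (censoring is purely administrative), measurement
error in 25(OH)D beyond the residual SD, and pleiotropy. Passing tests
therefore demonstrate that the estimator chain is correct and calibrated
under its own assumptions — not that those assumptions hold in any real
cohort.

## Simulation-study design

* **Recovery/coverage.** 200 replicate studies at n = 50,000 (cohorts
  scaled proportionally), full confounding, adjusted two-stage fits; the
  first 50 replicates check ≥90% CI coverage of the stage-1 truth (−1.33)
  and the MR truth (HR 1.20 per 20 nmol/L decrease), all 200 check that
  delta-CI empirical coverage lies in [0.90, 0.98]. Fits adjust for the
  full covariate set: genotypes are randomized so unadjusted fits are also
  consistent, but adjustment removes most hazard-ratio noncollapsibility
  attenuation from covariate frailty. The residual attenuation from the
  exposure noise itself (~5% of the ratio) is small relative to the
  interval width at this instrument strength.
* **Power.** 40 replicates per sample size; detection = two-sided z-test on
  the ratio at α (equivalently the (1−α) delta CI excluding HR = 1). At the
  default effect sizes, power is far below 50% at n ≈ 10,500 and rises
  several-fold by n ≈ 60,000, reproducing the qualitative underpowering of
  a ~10,500-person study.

Problem sizes (200/40 replicates, n up to 60,000) were chosen so the whole
study runs in minutes on one CPU while leaving Monte-Carlo error well
inside the asserted margins.

## Numerical and degenerate-input choices

* Exact stage-1 fits (zero residual) report F = ∞, partial R² = 1 rather
  than NaN.
* Missing genotypes propagate to a missing score (never zero); a
  participant missing a SNP is excluded from that score's analyses only.
  Missing adjustment covariates trigger complete-case exclusion from model
  fits; such rows stay in descriptive output.
* Category Cox fits drop empty-category dummies; on tiny samples where the
  category factor separates, the pipeline logs a warning and omits the
  observed category HRs instead of aborting.
* Identity-link Poisson rates are floored at 1e-10/person-year inside the
  likelihood; the linear fit uses Nelder–Mead on the exact Poisson
  log-likelihood.
* Allele orientation (which nucleotide is counted) is declared in
  configuration and never inferred from the data, keeping the instrument
  independent of the sample; VCF genotypes are read GT-only and
  multi-allelic records are rejected.
* `mortality_rate` and the truncation report are exact integer/float
  arithmetic; death rates are reported per 1000 person-years.

## Known limitations

One-sample MR with a single score: no MR-Egger/median sensitivity suite, no
two-sample variant, no weak-instrument-robust (Anderson–Rubin) intervals.
The delta CI is first-order and can undercover when the first-stage F is
small — the package warns below F = 10. The rate-shape comparison p-value
is a bootstrap construction, not a canonical test. The simulator's
covariate independence means balance tests on synthetic data are easier to
pass than on real cohorts.
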