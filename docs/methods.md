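# Methods

## Biological age (Klemera–Doubal)

The estimator treats each biomarker as a noisy linear readout of biological
age: regressing biomarker *i* on chronological age (CA) gives intercept
*q*ᵢ, slope *k*ᵢ and RMSE *s*ᵢ, and the per-biomarker implied age
(xᵢ − qᵢ)/kᵢ is combined across markers with precision weights kᵢ²/sᵢ²,
together with CA itself weighted by 1/s_BA²:

KDM = [ Σᵢ (xᵢ − qᵢ)kᵢ/sᵢ² + CA/s_BA² ] / [ Σᵢ kᵢ²/sᵢ² + 1/s_BA² ]

Numerical and estimation choices:

- **RMSE divisor.** √(RSS/n) by default; √(RSS/(n−2)) via
  `rmse_divisor="n-2"`. The two differ negligibly at survey scale.
- **s_BA.** The literature states its semantics (the dispersion of true
  biological age around CA) but rarely a concrete estimator. The default
  here is a variance decomposition: with BA_E the biomarker-only estimate
  (drop the CA terms from the formula), Var(BA_E − CA) is the sum of the
  true biological-age dispersion and the estimation-noise variance
  1/Σkᵢ²/sᵢ², so s_BA² = Var(BA_E − CA) − 1/Σkᵢ²/sᵢ², floored at 1e-6
  (with a warning) when the data are too clean to leave an excess. A fixed
  user-supplied s_BA is accepted for strict reproduction of external
  models; the method label is serialized with the model.
- **Training sample.** The model is trained on the same complete-case
  analytic sample it scores, matching single-cohort usage; an external
  training table can be used by fitting on one frame and scoring another.
- **Degenerate inputs.** Zero-slope biomarkers are retained with zero
  weight and a warning (they simply do not contribute); fitted sᵢ is
  floored at 1e-8 inside the weights so noiseless fits cannot divide by
  zero; constant CA raises.
- **Acceleration.** Residual of OLS of KDM age on CA with intercept, fit on
  the scored sample, so residuals average zero by construction.
  "Accelerated" is residual > 0; the threshold is configurable because the
  cutoff defining the binary outcome is a modelling choice, not a fact of
  the estimator.

Useful identities, all covered by tests: records lying on the fitted mean
trajectories score KDM = CA exactly for any s_BA; scores are invariant to
affine rescaling of any biomarker (unit changes); s_BA → ∞ recovers the
pure biomarker estimate and s_BA → 0 recovers CA.

## Dietary indices

**DI-GM.** Components are pure configuration (`DietComponentRule`): name,
direction, rule, scorable flag. The default roster has 14 components — 10
beneficial (avocado, broccoli, chickpeas, coffee, cranberries, fermented
dairy, fiber, green tea, soybean, whole grains) and 4 unfavorable (red
meat, processed meat, refined grains, high-fat diet) — with green tea
defined but unscorable in NHANES-like inputs, so scores span 0–13.
Beneficial components score 1 at or above the sex-specific median,
unfavorable ones below it; the high-fat component scores 1 when the energy
share from fat is below 40%. Component medians default to the analytic
sample's (weighted, when a weight column is supplied).

**CDAI.** Σᵢ (intakeᵢ − Meanᵢ)/Scaleᵢ over vitamins A, C, E, β-carotene,
selenium, zinc. The scale defaults to the standard error of the sex-specific
mean (`scale_kind="se"`); the conventional standard-deviation scaling is
available as `scale_kind="sd"`. The two differ only by a per-sex factor
√n, which rescales the index but not its ranking or median split; the
choice is recorded in the config and serialized outputs.

**Median splits.** The classic weighted median: the smallest value whose
cumulative weight reaches half the total, averaging with the next value
when the half is hit exactly (so equal weights reproduce the ordinary
median). Ties at the median go to "high", keeping at-median participants
in the higher-index group deterministically. Splits are weighted by
default, reflecting the survey design; an unweighted flag exists for
reproducing unweighted analyses.

## Survey-weighted logistic regression

Point estimates maximize the weighted pseudo-log-likelihood by Newton
iteration with step-halving; convergence is a gradient sup-norm below 1e-8
after internally normalizing weights to mean one (estimates and the
sandwich are invariant to any positive rescaling of the weights, which the
normalization also makes numerically explicit). Separation is flagged on
the scale-free coefficient |βⱼ|·sd(xⱼ) exceeding 15 — the intercept is
exempt, since its magnitude tracks covariate centering rather than
separation — and raises naming the offending term.

Variance is the Taylor-linearization sandwich B⁻¹GB⁻¹ with B the weighted
pseudo-information and G the between-PSU variability of weighted score
totals within strata, using the usual n_h/(n_h − 1) factor per stratum.
Strata holding a single PSU are handled with the "adjust" convention —
their score total is centered at the grand mean of all PSU totals (factor
1) — and logged rather than raised. A consequence used in the tests: with
every record its own stratum, the estimator reduces exactly to the HC0
heteroskedasticity-robust sandwich of ordinary ML logistic regression.
Confidence intervals use the normal 0.975 quantile on the log-odds scale by
default; Student t with the design degrees of freedom (PSUs − strata) is
optional. Weights pooled over multiple survey cycles are divided by the
number of cycles, the standard practice for combined releases.

Model frames are strict complete-case (dropped counts logged). Replicate-
weight variance (BRR/jackknife) and multiple imputation are out of scope.

## Study pipeline

Order of operations: exclusions → KDM fit/score → index scoring → median
splits → models. Exclusion steps (age floor > 45 years, complete
exposure/outcome, complete covariates, complete KDM biomarkers) telescope
exactly and are emitted as a plain-text flowchart. Index references,
medians and splits are computed on the age-restricted analytic sample, and
the stratified and unstratified analyses reuse the same KDM and index
columns, computed once.

Covariate sets: Model 1 = age, sex, race/ethnicity, marital status,
income–poverty ratio, smoking, alcohol, energy intake, BMI; Model 2 adds
CRP and WBC. Categorical covariates enter reference-coded. Model 1 is the
headline for stratified analyses, with Model 2 as the further-adjusted
sensitivity model. Stratified rows that cannot be estimated (empty stratum,
separation) are emitted with a not-estimable flag rather than aborting the
suite.

## Synthetic cohort generator

The generator exists to make every downstream stage verifiable by
parameter recovery, so its structure mirrors the working models of the
analysis:

- **Biomarkers** follow xᵢ = qᵢ + kᵢ(CA + δ) + N(0, sᵢ), where
  δ = ±`latent_shift_years` (default 10 y) is a latent biological-age
  shift whose sign is the participant's true accelerated status. The
  accelerated status itself is a Bernoulli draw from a logistic model with
  the planted exposure log-OR; planting the effect on the latent shift lets
  the downstream binary "KDM accelerated" inherit a known odds ratio
  without circular use of the estimator.
- **Signal-dominant regime.** The default residual SDs make the ten-marker
  panel jointly pin the latent deviation to about ±2 years
  (Σk²/s² ≈ 0.25), so the downstream accelerated flag reproduces the
  generative one essentially without misclassification and recovered ORs
  are sharp tests of the estimation machinery. Real biomarker panels are
  far noisier; passing recovery tests therefore demonstrates correctness
  of the estimators, not the statistical power achievable on real data.
- **Exposure** (30-day antibiotic use) defaults to a 12% prevalence
  independent of demographics — a randomized-exposure regime in which the
  adjusted OR equals the planted conditional OR exactly; logistic
  coefficients on age and sex are available for confounded scenarios.
- **Effect modification** is planted by scoring each synthetic
  participant's DI-GM and CDAI with the same deterministic scoring code
  and the same weighted age-restricted median splits the pipeline uses,
  then applying stratum-specific exposure log-ORs in the outcome models.
  Scenario constructors plant the default study conditions: overall ORs
  1.64 (accelerated) and 2.66 (diarrhea); low-DI-GM 3.32/3.77; low-CDAI
  2.37/3.60; double-low 3.76/4.39, with null effects elsewhere.
- **Design.** Participants are assigned cyclically (then shuffled) to
  strata and PSUs, so every stratum holds exactly `psus_per_stratum` PSUs
  (default 2); weights are i.i.d. lognormal (σ = 0.5), independent of
  outcomes given covariates, keeping weighted estimators consistent.
  Missingness is MCAR, matching the complete-case analysis assumption, and
  targets the KDM biomarkers plus CRP.
- **Reproducibility.** One substream per purpose (demographics, design,
  diet, exposure, outcomes, biomarkers, missingness), each keyed by the
  single seed, so edits to one block of the config do not perturb
  unrelated columns.

What the generator does *not* emulate: NHANES file layouts, real sampling
fractions or nonresponse adjustment, non-Gaussian biomarker distributions,
informative missingness, or a questionnaire-derived diarrhea definition
(diarrhea is generated directly as a binary; real-data users must define
their own derivation).

## Known limitations and interactions

- In Model 2 the WBC covariate is also a KDM biomarker, so for the
  accelerated outcome it partially encodes the latent shift being
  predicted; Model-2 accelerated ORs answer a different conditional
  question than the planted marginal-over-biomarkers effect and are
  expected to differ from it. This mirrors the real-data ambiguity of
  adjusting for inflammatory markers that also enter the biological-age
  score.
- Monte-Carlo problem sizes: recovery analyses in the reproduction script
  use cohorts of 250,000 (Monte-Carlo SE of roughly 2–4% per odds ratio);
  the test suite uses 50,000-record cohorts and a 200-replicate coverage
  experiment at n = 5,000.
- The design-based variance is validated by coverage against the planted
  OR under i.i.d. data within the stratified design; strongly clustered
  outcomes are not simulated.
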