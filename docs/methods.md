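# Methods

## Scope and model

The package operationalizes *brain maintenance* and *cognitive
maintenance* as deviations from normative aging: a machine-learning
model of chronological age is fitted to brain-structural features and,
separately, to cognitive test scores; each subject's out-of-fold
predicted age minus chronological age is the brain age gap (BAG) or
cognitive age gap (CAG). Negative gaps indicate a younger-appearing
profile. *Cognitive reserve* enters as the hypothesis that a reserve
proxy (premorbid IQ, education) predicts CAG independently of BAG.

### Age prediction

- Features are residualized per modality on confound sets
  {scanner, motion, sex, ethnicity, ICV} (gray matter) and
  {scanner, motion, sex, ethnicity} (white matter) by per-column OLS,
  then z-scored (sample SD, n−1). Residualization precedes
  standardization; the two operations commute with column subsetting
  and are idempotent. An alternate gray-matter set without the ICV term
  supports the cortical-thickness crosscheck.
- The default learner is an xgboost regressor with the selected
  hyperparameters (brain: depth 2, 180 estimators, learning rate 0.1;
  cognitive: depth 2, 140 estimators, rate 0.05); a randomized
  hyperparameter search over a user grid (scored by mean CV RMSE, ties
  toward smaller depth then fewer estimators) is provided, with depth
  range {1..5} as the default scan. Any fit/predict regressor
  satisfies the learner contract; a deterministic linear fallback is
  used where bit-exact tests need it. The pipeline, not the learner, is
  the contribution.
- Folds are assigned by hashing sorted subject ids through a seeded
  permutation, so fold membership is invariant to row order. Metrics
  (R², RMSE, MAE) are summarized over k folds × r repeats; the pooled
  predicted-vs-chronological Pearson r uses the first repeat's
  out-of-fold vector (reported as 0 with an `undefined` flag for a
  degenerate constant prediction).
- Permutation nulls shuffle age labels and recompute the full CV
  metric; empirical p = (exceedances + 1)/(n_perm + 1), which can never
  be zero and equals 1.00 × 10⁻³ for 0/1,000. A PCA-reduced variant
  (top 20 components of the standardized matrix) checks that the
  brain-vs-cognitive accuracy ordering is not an artifact of feature
  count.

### Gaps and associations

- Age-bias correction regresses the raw gap on intercept + age and
  keeps the residual; by construction the corrected gap has exactly
  zero sample correlation with age. The corrected gaps are used for the
  BAG–CAG correlation (Pearson, Fisher-z 95% CI); association models
  use the *raw* gap as outcome with age among the covariates, which
  matches a "Model 1 adjusted for chronological age" design.
- Model 1 covariates: {age}. Model 2: {age, sex, education, ethnicity,
  BMI, other gap}; when education or premorbid IQ is the predictor the
  other of the pair is included and BMI dropped. Continuous variables
  (outcome, predictor, covariates) are z-scored so coefficients are
  standardized βs; binary 0/1 codes are left as is. Model 2 is fitted
  when the Model 1 coefficient is nominally significant (α = .05),
  mirroring the staged design.
- The correlated-samples statistic
  Z = (β₁ − β₂)/√(σ₁² + σ₂² − 2ρσ₁σ₂) takes ρ from the age-adjusted
  gap correlation; it reduces to the independent-samples Z at ρ = 0 and
  is two-sided throughout. Standard errors recovered from printed 95%
  CIs use half-width / 1.96.
- FDR correction is Benjamini–Hochberg step-up (delegated to
  statsmodels), applied per results-table family (one family per model
  tier, one for the Z comparisons, one for post hoc tests); the family
  boundaries are a package choice since no finer grouping is published.
  Rows with p < .05 but corrected p ≥ .05 carry a *trend* annotation —
  a report label, not an inference rule.
- Outlier sensitivity excludes subjects outside
  [Q1 − 3·IQR, Q3 + 3·IQR] on any analysis variable; quartiles use
  linear interpolation (type 7), fixed because the convention is
  otherwise unstated.

### Lifestyle scoring

Per phase, one point each for alcohol ≤ 7 units/week (abstinence and
light drinking both healthy, strictly more than 7 unhealthy),
never-smoker, and ≥ 2.5 h/week of moderate-to-vigorous activity; both
numeric boundaries are inclusive-healthy. A missing behavior marks the
phase unobserved rather than scoring zero. Indices are standardized
within phase (questionnaires differ between phases) before trajectory
modelling. The cumulative score is the mean of raw 0–3 indices over
observed phases (mean rather than sum: unbiased when subjects with four
or five phases are mixed; a summed variant sits behind a flag because
the published cumulative range is inconsistent with a 0–3 average). The
continuous variant sums, per phase, z-scored activity, z-scored negated
alcohol, and the binary never-smoker point with equal weights (the
published analysis does not print its formula), plus per-behavior
cumulative measures: mean alcohol units and a persistent-smoker
indicator (current smoker at ≥ 3 phases).

### Latent class growth analysis

- Model: y_ij = polynomial_k(t_j) + e_ij for subject i in class k,
  quadratic by default, with class mixing proportions π_k and a
  residual variance **shared across classes and phases** (homoscedastic
  LCGA, within-class random effects fixed at zero — the convention when
  the published variance structure is unstated). Time scores are
  (mean phase age − 53)/10, i.e. [0, 0.3, 1.1, 1.5, 1.7] for phase mean
  ages [53, 56, 64, 68, 70].
- Estimation: EM with full-information maximum likelihood — subject i
  contributes a product of normal densities over their observed phases
  only, so subjects missing a phase stay in the likelihood. The M-step
  is a responsibility-weighted polynomial least squares per class; the
  within-start log-likelihood is non-decreasing every iteration and is
  asserted in tests. Multi-start protocol: 500 random starts capped at
  20 iterations, the best 20 continued to a 10⁻⁶ log-likelihood
  tolerance (the published "iterations: 20" is read as the
  initial-stage cap; 20 EM iterations rarely converge fully). Starts
  draw initial responsibilities from a Dirichlet; runs that collapse a
  class proportion (< 10⁻⁸) or the residual variance are discarded and
  logged. For a single class the residual variance is clamped at 10⁻¹⁵
  so the noiseless least-squares limit stays defined.
- Classes are relabelled by descending fitted baseline value, so the
  least favorable class is last and serves as the dummy-coding
  reference in association models.
- Fit indices: AIC = −2LL + 2p; BIC = −2LL + p·ln n;
  aBIC = −2LL + p·ln((n + 2)/24); entropy = 1 − Σᵢₖ(−π̂ᵢₖ ln π̂ᵢₖ)/(n ln K),
  1 for K = 1; p = K(order + 1) + K (coefficients, K − 1 free weights,
  variance). Standard definitions adopted where the published formulas
  are not printed.
- Enumeration: candidates K = 1..k_max are filtered on entropy ≥ 0.8,
  smallest class ≥ 5%, and BLRT p < .05 (K = 1 has no BLRT and passes
  that filter); the lowest BIC among survivors wins, ties broken by
  aBIC then AIC; with no survivor the best-BIC candidate is returned
  flagged. Every exclusion is recorded in an audit trail. The BLRT
  simulates bootstrap datasets from the fitted (K−1)-class model with
  each subject's missingness pattern preserved, refits both models, and
  compares 2ΔLL to the bootstrap distribution with
  p = (exceedances + 1)/(n_ok + 1); failed refits are excluded and more
  than 20% failures is an error. The VLMR likelihood-ratio test is not
  implemented (its reference-distribution approximation is not
  reproducible from published material); its fields are absent, not
  faked.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any real cohort's marginals beyond published ranges.

- n = 537 subjects; age truncated-normal (69.75, 5.08) on
  [60.34, 82.76]; covariates with realistic marginals (17.5% female,
  5.4% non-white, education ~ N(16.75, 4.4), premorbid IQ ~ N(100, 15),
  27% post-upgrade scanner, gamma-distributed motion, ICV ~ N(1.5 × 10⁶,
  1.4 × 10⁵) mm³).
- Features: feature_ij = √s·sign_j·z(age_i + gap_i) + √c·z(conf_ij) +
  √(1−s−c)·ε_ij, where s is the per-feature signal fraction (brain 0.20
  over 100 features, cognitive 0.05 over 20), c = 0.10 the confound
  share (cognitive features carry no scanner/ICV structure), and gap_i
  the planted per-subject deviation (SD 4 years brain, 8 years
  cognitive). Gap SDs bound achievable prediction accuracy from above;
  together with the signal fractions they were chosen once so that
  default cohorts land near out-of-fold R² ≈ 0.4 (brain) and ≈ 0.1
  (cognitive), reproducing the published accuracy ordering. The reserve
  covariate (standardized premorbid IQ) loads on the cognitive gap only
  (default standardized effect −0.3); an optional lifestyle exposure
  effect loads on the brain gap only.
- Lifestyle panels: three default trajectory classes (low-improving
  41.2%, high-declining 24.2%, moderate-consistent 34.6%) on the
  standardized index scale, evaluated at the transformed time scores,
  plus N(0, 0.35) noise. The latent level is quantized to the 0–3 index
  and raw behaviors are constructed to realize exactly that index
  (which behaviors carry the points follows a per-subject priority,
  fixed across phases so smoker status is stable), so binary scoring
  round-trips by construction. Class separation and noise were set so
  the planted three-class structure is recoverable with entropy ≥ 0.8
  at the default sample size — the condition the analysis stage is
  meant to exercise; weaker separation makes enumeration collapse to
  one class on quantized indices.
- Missingness removes at most one uniformly chosen pre-final phase per
  subject (probability 0.30), never the final phase, matching a design
  that requires at least four observed phases.
- A single numpy Generator seeded from the config drives everything;
  identical configs produce byte-identical tables. The planted-truth
  table (gaps, class memberships, lifestyle latents) is written to a
  separate `.truth.tsv` and is read only by tests.

**What the generator does not emulate:** item-level cognitive tests,
image-derived feature covariance structure (features are conditionally
independent given the latent), non-linear age effects, cohort attrition
patterns, or realistic behavior dynamics (e.g. smokers quitting in a
correlated way). Passing tests therefore show the pipeline recovers
planted structure under its own assumptions, not that the effects are
detectable in any particular real cohort.

## Problem sizes and numerical choices

- Pipeline defaults: 10-fold CV × 5 repeats; permutation nulls off by
  default (the reference setting is 1,000 permutations; they recompute
  the full CV per permutation and are enabled per run). Enumeration
  defaults to 50 starts / 5 finals and 24 bootstrap draws per BLRT —
  with B draws the smallest attainable p is 1/(B + 1), so B ≥ 20 is
  required for the p < .05 rule to be satisfiable; bootstrap refits use
  reduced multi-start settings.
- Simulation-based tests use scaled problem sizes chosen to keep the
  suite fast while leaving clear margins: 20 replicate cohorts for the
  accuracy ordering, 100 seeds at n = 500 with 3-SD class separation
  for enumeration recovery, 5,000 replicates for Z-test type-I
  calibration, 200/1,000 replicates for coefficient recovery and
  type-I checks of the association models.
- Ties in hyperparameter search break deterministically (RMSE, depth,
  estimators, draw order). Quartiles are type-7. Degenerate inputs
  (zero-variance features, constant prediction vectors, zero age
  variance, < 4 observed lifestyle phases) raise or flag rather than
  propagate silently.

## Known limitations

- LCGA assumes homoscedastic normal residuals; on quantized 0–3
  indices this is an approximation, and information criteria can favor
  extra classes on such data (the default enumeration range stops at
  K = 3).
- The BLRT p-value resolution is limited by the bootstrap draw count.
- Robust (sandwich) standard errors for the growth model are not
  implemented; reported uncertainties for LCGA parameters are limited
  to what the posterior and likelihood provide.
- Associations are cross-sectional OLS; no mediation, mixed-effects, or
  causal machinery.
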