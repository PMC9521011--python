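# Methods

This note documents the statistical machinery in `dnamcvd`: what each stage
assumes, the tunable parameters and their defaults, what the synthetic cohort
generator does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Data model and conventions

Methylation is represented as beta values (methylated over total intensity,
in [0, 1]); probes are opaque cg-identifiers with no genomic coordinates.
The on-disk convention is probes-as-rows (series-matrix style); in memory
everything is samples × probes.  Missing calls are NaN.  Sex is coded
0 = female, 1 = male everywhere a model needs a number; this coding is part
of the weight-table contract — changing it would silently corrupt every
shipped or exchanged weight table.

Probe-level QC follows standard array practice: an exclusion list of
cross-reactive/polymorphic probes (supplied by the user; tests use synthetic
lists), masking of calls with detection p-value above 0.01, and per-probe
mean imputation of the resulting missing values.  Mean imputation is the
simplest deterministic rule that keeps beta in [0, 1] and preserves probe
means; it ignores correlation between probes, which is acceptable because
downstream fits only consume marginal probe columns.  Samples failing
bisulphite-conversion controls are expected to be removed upstream — raw
control-probe intensities are outside the data model, so the reader simply
accepts a pre-filtered sample list.

## Surrogate training

For one risk factor `y > 0` measured on `n` samples:

1. **Centre ANOVA.**  One-way ANOVA of `log y` across recruitment centres.
   If p < 0.05 (conventional level; configurable) the marker is treated as
   centre-heterogeneous and all subsequent steps carry a centre
   random intercept.  The threshold is recorded in the fitted model.
2. **EWAS screening.**  Per probe: `log y ~ beta_j + age + sex`.  The probe
   scan is computed by the Frisch–Waugh identity (residualise `y` and every
   probe on the covariate design once, then a vectorised simple regression
   per probe), which makes the scan O(nP).  On the mixed route the variance
   components are estimated **once** from the covariate-only model and all
   variables are whitened by the implied covariance before the scan: the
   probe's contribution to the variance components of a genome-wide scan is
   negligible, and re-estimating them per probe would cost three orders of
   magnitude more.  Fixed-route p-values are two-sided t tests (n − 4 df);
   mixed-route p-values use the large-sample normal approximation, because
   small centre counts make finite-df corrections unstable.  Probes are
   ranked by ascending p, ties broken by probe id; `ceil(top_fraction · P)`
   probes (minimum 1) are retained, default `top_fraction = 0.01`.
3. **Penalised fit.**  The objective is
   `(1/2n)‖y − Xw − Zc − b₀‖² + λ‖w_std‖₁` with age/sex/intercept
   unpenalised and the penalty applied on internally standardised probe
   columns (the glmnet convention); returned weights are rescaled to the
   original beta scale.  Unpenalised covariates are handled exactly by
   partialling them out of `y` and `X` before the L1 solve.  λ is selected
   by 10-fold cross-validated mean squared prediction error on a 100-point
   log grid spanning four decades below `λ_max = maxⱼ|x̃ⱼᵀỹ|/n` (the smallest
   penalty that zeroes every weight).  Ties in CV error resolve to the
   larger λ.  The inner solver is coordinate descent at tolerance 1e-12, so
   the KKT conditions hold at ~1e-8 and are asserted at 1e-6 in the tests.

**Mixed-effect LASSO.**  With a centre random intercept the model maximises
the marginal Gaussian log-likelihood minus the L1 penalty.  The fit
alternates (a) an exact variance-component update — the marginal likelihood
of a random-intercept model is profiled down to a scalar function of the
variance ratio θ = σ²_b/σ²_e and minimised on [0, 10⁴] with an explicit
boundary comparison, so a no-between-variance solution comes back as exactly
θ = 0 — and (b) an L1 update of the fixed effects on whitened data, where
whitening subtracts `c_g = 1 − sqrt(σ²_e/(σ²_e + m_g σ²_b))` times the group
mean from each group's rows (identity when σ²_b = 0, mapping the covariance
to σ²_e·I otherwise).  λ is chosen by CV on the first whitened problem and
then held fixed.  Convergence is declared when the relative change of the
penalised whitened objective drops below 1e-6 (typically 2–7 iterations);
exceeding 100 iterations raises with the objective trail and current
variance components.  Random intercepts are deliberately **not** part of the
prediction rule: surrogates must be computable in cohorts whose centres were
never seen, so out-of-cohort centre effects are set to zero.

When the true between-centre variance is zero, the ML estimate lands on the
boundary with roughly probability one half (otherwise it is a small positive
sampling artefact); on the boundary the mixed fit coincides exactly with the
plain LASSO, which is the reduction property the tests certify.

**Validation.**  Pearson correlation of predicted vs observed log marker in
held-out data (t distribution, n − 2 df), plus a fixed-effect Fisher-z
meta-analysis (weights n − 3) pooling external studies; a DerSimonian–Laird
random-effects variant is available since study heterogeneity across arrays
and populations is common.  A surrogate counts as validated when p < 0.05
both internally and in the pooled external estimate.

## Composite score

Candidate features (newly trained surrogates, literature weight tables,
precomputed columns such as clock outputs or cell proportions) are assembled
in panel order and standardised to mean 0, sd 1 (denominator n − 1) within
the population being scored — the score is interpreted as standardised
within-cohort; training-set statistics can be frozen for deployment.
The missing-probe policy when applying literature tables is lenient by
default: absent probes contribute 0 (no renormalisation, keeping published
weights as printed), with a warning, and an error above 20% absent.

The score is defined by stability-selected elastic-net Cox regression:

- per fit: Breslow partial likelihood, penalty `λ[α‖β‖₁ + (1−α)‖β‖²/2]`,
  α = 0.5 by default (neutral between ridge and lasso; sensitivity runs at
  α ∈ {0.1, 0.9} live in the test-suite fixtures), λ on a 30-point log grid
  from the data-driven `λ_max` down two decades;
- λ selection: 10-fold CV stratified by event status (avoids event-free
  folds), scoring Harrell's concordance of the held-out linear predictor.
  The default rule is the glmnet **1-SE convention**: the largest λ whose
  mean CV concordance is within one standard error of the optimum.  The
  plain optimum is available (`lambda_rule="best"`), but in the
  stability-selection setting it systematically under-penalises — noise
  features then clear the 50% selection threshold — so the parsimony rule is
  the default.  Concordance is maximised by default; a flag preserves the
  literal minimising reading of the procedure's description;
- stability loop: the CV-tuned fit is repeated on `n_perm` (default 1,000)
  random subsamples of size `ceil(0.8 · N)` drawn without replacement
  (1,443 of 1,803), CV re-run inside each subsample so every repetition is
  self-contained; a feature is selected when its coefficient is nonzero in
  at least `freq_threshold` (default 0.5) of the subsamples; its score
  coefficient is the mean of its nonzero coefficients (zeros excluded —
  below-threshold features still get a reported mean for diagnostics);
- the paper-style two-pass protocol (first fit with age and sex, then refit
  without them because several surrogates already embed age/sex terms) is
  expressible through `exclude_features`.

The packaged ten-feature coefficient table reproduces the published
composite weights (only DNAmHDL negative, −0.4473); `compute_cvd_score` is a
pure linear combination with no intercept, so unit-vector inputs return the
coefficients themselves.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, with known ground
truth; defaults mirror the study conditions of a single-country prospective
cohort: 1,803 samples, four recruitment centres, administrative censoring at
18 years, baseline hazard 0.01/year (≈16% cumulative incidence), age uniform
35–75, 62% female, five log-scale biomarkers of which three carry planted
between-centre heterogeneity (sd 0.2 on the log scale) and two do not.

- **Betas** are probe-specific logit-normal (logit mean uniform in [−3, 3],
  logit sd uniform in [0.3, 1.0]), clipped to [0, 1] — bounded, unimodal,
  heteroscedastic across probes like real arrays.
- **Markers**: `log y = intercept + Σ w_j β_j + age·a + sex·s + centre offset
  + N(0, noise_sd)`.  Planted weights have random sign and per-probe
  contribution sd uniform in `[0.5, 1.5] · effect_size_sd` (weights scaled
  by 1/sd(β_j); causal probes drawn among probes with beta sd ≥ 0.02).
  Parameterising by contribution rather than raw weight keeps every planted
  probe identifiable — with raw Gaussian weights a sizeable fraction of the
  "causal" probes contribute essentially nothing and no method could recover
  them, which would make support-recovery experiments meaningless.  Default
  `effect_size_sd = 0.15` with `noise_sd = 0.5` yields held-out surrogate
  correlations in the 0.4–0.7 range typical of published DNAm surrogates.
- **Events**: exponential times with rate `baseline_rate · exp(lp)`, where
  `lp` is a linear combination of the standardised true CpG signals (default
  weights follow the packaged composite coefficients for the five in-study
  markers), censored administratively.  Constant hazard gives closed-form
  checks (event fraction `1 − exp(−rC)`); a Weibull shape is a natural
  config extension but is not implemented.
- **Nested case-control**: incidence-density sampling — controls for each
  case are drawn from subjects event-free and still under follow-up at the
  case's event time, matched on sex and centre with an age caliper (default
  ±5 y).  Cases are processed in event-time order (ties by sample id) and
  each subject enters the subset at most once, so sample ids stay unique;
  classic incidence-density sampling would allow reuse, and the no-reuse
  variant slightly depletes risk sets in small cohorts.

Not emulated: probe-level batch effects, cell-composition confounding,
genotype-driven methylation, and competing risks (the real training outcome
censors at incident cancer diagnoses; the generator has a single event
type).  Passing tests therefore demonstrate correctness of the machinery
under the stated generative assumptions, not robustness to those real-data
complications.

## Evaluation

- **Horizon censoring** relabels events after the horizon as non-events and
  keeps the subjects (stable specificity denominators across the sweep); a
  variant that drops late cases instead is a flag.  Sweeps run from 18 down
  to 2 years in 1-year steps by default (17 rows); a single-class horizon
  emits a missing-AUC row with a warning rather than failing the sweep.
- **ROC**: built on the fitted logistic linear predictor when matching
  covariates are supplied (model-level AUC) and on the raw score otherwise,
  in which case the AUC equals the Mann–Whitney rank statistic exactly.
  AUC variance is DeLong's (midrank placements), the operating point
  minimises the distance to the top-left corner, and predictor ties use the
  standard midrank convention.
- **Harrell's C**: pairs comparable iff the shorter time ends in an event;
  time ties are not comparable; prediction ties count 1/2.  The variance is
  a leave-one-subject-out jackknife computed in closed form from per-subject
  pair sums — O(n²) once, no refitting.  Cox fits use Breslow ties
  (statsmodels PHReg); the hazard ratio is reported per SD of the score with
  a Wald interval.  A perfectly separating score has no finite Cox optimum;
  the evaluator then falls back to ranking by the raw standardised score
  with a warning, leaving the concordance well-defined.
- **compare_models** treats models as named column bundles, so a composite
  score, a refit traditional-risk-factor bundle (age, sex, diabetes,
  smoking, blood pressure, cholesterol columns) and enriched combinations
  are evaluated identically.  The traditional comparator is a within-study
  refit, not a published external calibration; an externally computed score
  can be supplied as a precomputed column.

## Problem sizes and determinism

Test and acceptance experiments use scaled cohorts chosen for statistical
headroom rather than realism of scale: 800 samples × 500 probes with 10
causal CpGs for support recovery, 600 samples × 18 features with 100
subsamples for stability selection, 1,200 samples for null-behaviour checks.
The EWAS-dimension default in the generator is 2,000 probes; all ranking and
selection logic is dimension-agnostic.  Every stochastic component takes an
explicit seed and the generator is bit-reproducible for identical
configurations; stability-selection frequencies are reproducible bit-exactly
and equivariant under feature permutation (coefficients agree to coordinate-
descent tolerance, ~1e-6).

## Known limitations

- The mixed-route EWAS shares one variance-component estimate across probes;
  probes with very strong effects would merit per-probe re-estimation.
- The mixed-LASSO λ is fixed after the first whitening; a λ re-search per
  outer iteration would be more faithful to a joint optimisation but is
  rarely consequential because the whitening changes little after the first
  variance update.
- DeLong intervals are symmetric on the AUC scale and can touch the [0, 1]
  clip at extreme AUCs; a logit-scale variant is not implemented.
- Weight tables assume probe identity across array generations; no liftover
  or cross-array harmonisation is attempted.
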