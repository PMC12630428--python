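# Methods

## Estimands and identification

For a binary exposure `X`, baseline confounders `C`, intermediate confounders
`L = (L_1..L_4)`, mediators `M = (M_1..M_3)` and outcome `Y`, the package
estimates counterfactual outcome means under joint assignments
`(x_direct, x_mediator)`: `x_direct` is the exposure value driving `L` and
the outcome model, `x_mediator` the value driving the mediator block.  Three
scenarios suffice: `p(0,0)`, `p(1,0)`, `p(1,1)`.  Binary outcomes are
contrasted on the odds-ratio scale (TCE, NDE, NIE as in the README; the
decomposition `TCE = NDE × NIE` is an algebraic identity of the three
prevalences and is asserted to 1e-10 at run time); numeric outcomes use mean
differences with `TCE = NDE + NIE`.

Because intermediate confounders are present, *natural* direct and indirect
effects are not nonparametrically identified.  The implementation computes
their randomized **interventional analogues**: in scenario
`(x_direct, x_mediator)` the mediator block is drawn from its distribution
under `x_mediator` marginalized over an *independent* draw `L~` of the
intermediate confounders under `x_mediator`, while the outcome is evaluated
at a separate draw `L*` under `x_direct`.  This is the standard resolution in
the g-formula mediation literature; it coincides with natural effects when
exposure–confounder interaction is absent from the true laws.  Identification
otherwise requires the usual no-unmeasured-confounding assumptions for
`X→Y`, `X→M` and `M→Y` (the last conditional on `L`), plus correct
specification of every component model.

The three mediators form one block: a single indirect effect is estimated
through all of them jointly, because their mutual causal ordering is not
assumed known.  The within-block simulation order (arrest → gang →
noncompletion, the temporal order of measurement) is configurable and
recorded in the output metadata; the block NIE is invariant to it only in
expectation of the block draw, not per-path.  The single-mediator sensitivity
model re-roles the other two mediators as intermediate confounders (appended
to the L block in temporal order), which *does* commit to them preceding the
primary mediator.

## Estimation pipeline

1. **Component models** — fitted by hand-written IRLS (logit) or the normal
   equations (identity), on the listwise-complete analysis rows.  IRLS uses
   step-halving, so the (penalized) deviance is monotone non-increasing, and
   iterates to gradient tolerance 1e-8 (max 100 iterations).  Wald
   covariances come from the observed information.
2. **Separation** — a 2% mediator makes quasi-complete separation likely in
   bootstrap resamples.  Divergence (|b| > 15 or non-convergence) triggers a
   refit with ridge penalty λ = 1e-4 per observation on non-intercept terms;
   the model is flagged `converged=False` with an annotation that propagates
   into all downstream metadata.
3. **Simulation** — `copies` (default 100) replications of the empirical `C`
   rows; `L*`, `L~`, `M` drawn sequentially by inverse-uniform; `Y` evaluated
   as its conditional mean rather than drawn (same estimand, one less layer
   of noise).  The three scenarios share one uniform stream per variable
   (common random numbers), which cancels most Monte-Carlo noise out of the
   effect contrasts: at copies=20 and n=4599 the residual MC error on a log
   odds ratio is below 0.01, an order of magnitude under sampling noise.
4. **Bootstrap** — full-procedure: rows resampled with replacement, every
   model refitted, effects re-simulated.  Default B = 50 with normal-based
   95% CIs computed on the log-OR scale around the full-sample point and
   exponentiated; ≥ 200 resamples are recommended for production use.
   Failed resamples are dropped and counted; more than 20% failures raises
   under strict mode.
5. **Missing data** — chained-equations imputation (below), bootstrap within
   each completed dataset, Rubin pooling of log-scale effects with the
   bootstrap variance as within-imputation variance.

An exact-enumeration oracle computes the same counterfactual prevalences by
summing over all 2^(|L|+|M|) configurations conditional on each `C` row — no
simulation error.  It requires the post-exposure block to be binary (the
default) and is the reference every Monte-Carlo path is tested against.

## Synthetic cohort generator

The generator simulates forward through a DAG with the structure the
estimator assumes, with every structural coefficient known, so parameter
recovery, null behaviour and coverage can be tested without access to any
restricted cohort data.

* **Baseline confounders (always complete, as perinatal/childhood data in a
  birth cohort):** female sex (51%), parental smoking (73%), parental
  separation (57%), and two standardized numeric scores — `risk_score`
  (standing in for the sociodemographic/health risk composites and related
  family-level confounders) and `hyperactivity` (the comorbidity adjuster).
  These five compress the ~10 confounders a real analysis would carry; the
  compression keeps the enumeration oracle and the tests readable while
  still confounding every arrow.
* **Exposure:** high conduct problems, logistic in `C`, marginal 31%.
* **Intermediate confounders (binary):** peer deviance (47%), adolescent
  smoking (6%), adolescent alcohol use (25%), peer drug use (13%).
* **Mediators (binary, temporal order):** police arrest (4%) → gang
  membership (2%) → school noncompletion (43%), each conditional on the
  earlier ones (positive co-occurrence; the joint prevalence of e.g.
  arrest ∧ gang is not pinned down by published marginals, so the overlap
  implied by the conditional coefficients is a free modelling choice).
* **Outcomes:** hazardous alcohol use (22%), current illicit drug use (14%),
  plus two numeric alcohol subscales — consumption (range 0–12, mean ≈ 3.2)
  and problems (range 0–28, mean ≈ 1.8) — generated as *rounded,
  range-clipped* linear responses, a deliberate deviation from pure
  linearity that mimics bounded questionnaire scores.  Their means are not
  published; the defaults are chosen as plausible for a young-adult cohort
  where heavy consumption is common and consequences rarer.

Structural coefficients are fixed, documented log odds ratios chosen to
reproduce the qualitative pattern of the motivating study: modest
exposure→mediator arrows (0.45–0.55), strong arrest/gang→drug-use arrows
(1.3, 1.9), weak noncompletion→outcome arrows, a small direct X→Y arrow, and
nonzero confounding on every path.  Intercepts were solved once by 1-D root
finding on a semi-exact marginal surface (exact enumeration of the binary
post-baseline block, averaged over 200,000 sampled `C` rows) so that the six
key marginals match the emulated cohort's descriptive table; the solved
values are frozen as constants, making `default_pelotas_params()` pure.

**Missingness** is imposed separately: each maskable cell (intermediate
confounders, mediators, outcomes — never baseline variables or the exposure)
is masked with logistic probability depending on the exposure (+0.50
log-odds), sex, risk score and hyperactivity, reproducing the
attrition-associated-with-exposure pattern of real cohorts.  The per-column
intercept is solved on the cohort at hand so the realized mean cell rate
equals the configured rate (default 0.06, which leaves ≈ 52% of rows fully
complete, matching the emulated study's complete-case fraction).  The
mechanism is MAR by construction — the mask never depends on the masked
value.

**What the generator does not emulate:** joint distributions beyond the
marginals and the qualitative DAG; longitudinal repeated measures;
measurement error in the instruments; item-level SDQ/AUDIT scoring (cohorts
arrive pre-scored); informative (MNAR) attrition.  Passing tests therefore
demonstrate correctness of the estimator under its own assumptions — not
robustness to misspecification on real data.

**Truth computation.** `true_mediation_effects` enumerates the binary
post-exposure block exactly and averages over a 150,000-row `C` sample
(needed because two baseline scores are numeric); the Monte-Carlo error this
leaves on a counterfactual prevalence is ≈ 1e-3 at most and is verified in
the tests against an independent 10^6-draw forward simulation.  For the
numeric outcomes the truth uses the closed-form mean of a clipped normal;
rounding to integers is ignored there (bias ≪ 0.01 on these scales).

## Multiple imputation

Chained equations with main-effects conditional models: logistic draws for
binary columns, linear draws with noise for numeric ones, coefficients
perturbed by a draw from their estimated sampling distribution (and the
residual variance from its scaled inverse-chi-square) each sweep.  Every
column serves as a predictor in every conditional model, so the imputation
model nests the analysis models (congenial); columns outside the analysis
roles act as auxiliaries.  Defaults: m = 40 completed datasets, 10 sweeps
(the dataset count follows the emulated study; the sweep count is standard
practice, as the source does not state one).  Rubin CIs use the large-sample
normal reference, matching the normal-based bootstrap CIs; a small-sample
Barnard–Rubin correction is deliberately not the default.  No
predictive-mean-matching, multilevel, or ordinal models.

## Study pipeline

`run_study` executes dichotomization (at-or-above cutpoints, e.g. SDQ
conduct ≥ 4, AUDIT ≥ 8), a descriptive table (Wald CIs on proportions by
default, Wilson behind a flag), staged association tables
(exposure→mediator: unadjusted / baseline / +comorbidity; mediator→outcome:
unadjusted / adjusted / +comorbidity / +all mediators, with the exposure
added to adjusted mediator→outcome models), mediation across three
adjustment tiers, and the sensitivity analyses (single-mediator,
complete-case vs imputed, numeric subscales).  With the synthetic defaults
the comorbidity tier adds the `hyperactivity` score only — the generator
compresses the baseline and intermediate comorbidity adjusters of a real
analysis into that one variable.  PM is rendered "n/a" under inconsistent
mediation or |ln TCE| < 0.01 (the threshold is an implementation choice).
All stage seeds derive from the config's root seed; report regeneration is
byte-identical.  Exposure–mediator adjusted models condition on baseline
confounders (+ hyperactivity) only, not intermediate confounders — users who
consider the intermediates pre-mediator confounders can pass custom stages.

## Numerical choices and problem sizes

* IRLS gradient tolerance 1e-8; ridge fallback λ = 1e-4 per observation;
  separation threshold |b| > 15.
* Scenario simulation chunks at ≤ 2·10^6 rows to bound memory.
* Wald p-values are two-sided, printed to 3 decimals with a "<0.001" floor.
* Test-suite problem sizes are chosen to keep the full suite near ten
  minutes on one core while leaving every check decisively powered:
  calibration at n = 10^6; oracle agreement at copies = 1000; recovery and
  coverage over 50 cohorts of n = 4599 with B = 50 and copies = 20 (at which
  the residual MC noise is negligible next to sampling error); null suites
  at n = 10^5 (point nulls) and 20 permutation replicates.

## Known limitations

* Interventional-analogue effects, not true natural effects, when
  exposure–confounder interactions exist; this mirrors the identification
  limits of the design, not a software shortcut.
* The bootstrap default B = 50 gives noticeably noisy SEs; it is kept as the
  default for comparability and should be raised for real analyses.
* No time-varying-exposure g-formula, no IPW/doubly-robust estimators, no
  exposure–mediator interaction decompositions, no survival outcomes.
* The ridge fallback under separation shrinks rare-mediator coefficients
  slightly toward zero; affected fits are always annotated.
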