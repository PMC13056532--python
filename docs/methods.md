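# Methods

This note documents the statistical procedures, the synthetic data-generating
process, numerical choices, and known limitations of the `maihda` package.

## The MAIHDA design

MAIHDA treats each combination of categorical exposures as one stratum and
fits a two-level random-intercept model with individuals (level 1) nested in
strata (level 2). Compared with a saturated fixed-effects regression over
all interactions, the multilevel formulation is parsimonious, produces
precision-weighted (shrunken) estimates for small strata, and cleanly
separates additive from multiplicative structure: if the stratum means are
just the sums of individual behaviour effects, adding those main effects to
the fixed part removes (almost) all between-stratum variance.

Here the strata are the 48 = 2×2×2×2×3 combinations of five coded lifestyle
behaviours. Keys are 5-digit strings in the fixed order (sleep, fruit & veg,
alcohol, physical activity, smoking); digits 1–4 are 1 = meets the guideline,
and digit 5 is 0 = previous, 1 = current, 2 = never smoker. The digit order
is hard-coded; empty strata are retained everywhere with n = 0 and receive
fixed-part-only predictions, which is precisely the small-stratum advantage
of the approach.

### Recoding and exclusions

Guideline thresholds: sleep 7–9 h/day (both endpoints meet), ≥ 5
portions/day of fruit and vegetables, ≤ 14 units/week of alcohol ("no more
than" is inclusive), and ≥ 150 min/week moderate **or** ≥ 75 min/week
vigorous activity (a logical OR; no combined-equivalence scoring). Weight
status uses half-open BMI intervals [0, 18.5), [18.5, 25), [25, 30),
[30, ∞); 30.0 kg/m² is classified obese (WHO convention), making the four
categories an exact partition of the positive axis.

Handling of missingness is complete-case. The exclusion cascade drops, in
this fixed order: missing lifestyle codes, missing confounders, missing BMI,
underweight, and — for the binary contrasts — the weight-status category
outside the contrast (obesity vs. normal excludes overweight; overweight vs.
normal excludes obese). Each record is counted under the first applicable
reason only, so the ledger balances exactly: input = retained + Σ reasons.

### Estimation

**Linear.** `y = Xβ + Zu + e` with one grouping factor. For a variance
ratio ψ = σ²_u/σ²_e the GLS solve and all determinants reduce to per-stratum
sufficient statistics (Woodbury on exchangeable blocks), so one evaluation
of the profiled criterion is O(q·p²) after a single O(n·p) pass. The REML
(default) or ML criterion is minimised over log ψ by bounded scalar search
(absolute tolerance 1e-10 on log ψ), with the ψ = 0 boundary checked
explicitly: if the between-stratum mean square falls below the within mean
square the estimate truncates at σ²_u = 0 and the fit is flagged. On
balanced designs with interior optima this reproduces the one-way ANOVA
closed form (σ̂²_e = MS_within, σ̂²_u = (MS_between − MS_within)/n_per_group)
to numerical precision, and it matches lme4's `lmer` REML fits to ~6
significant digits in tests. Standard errors for (σ²_u, σ²_e) come from the
numerically differentiated observed information of the restricted
log-likelihood; at the boundary the Wald approximation for σ²_u does not
apply and its SE is reported as NaN.

**Logistic.** `logit P(y=1|u_j) = x'β + u_j`, `u_j ~ N(0, σ²_u)`. The
marginal likelihood integrates u_j out per stratum by Gauss–Hermite
quadrature adapted per stratum: nodes are centred at the posterior mode
(vectorised Newton across strata) and scaled by the Laplace curvature, which
keeps the default order 15 accurate for strata of any size. Identical
(stratum, covariate-row, outcome) rows are aggregated with weights first, so
models whose predictors are all categorical collapse to a handful of rows
per stratum and the null-model fit is effectively O(48). Maximisation is
L-BFGS-B over (β, σ_u ≥ 0) with analytic gradients computed as posterior
expectations of the complete-data score under the same quadrature rule;
fits agree with lme4's `glmer` at nAGQ = 15 to ~5 decimals in tests. The
level-1 variance is never estimated; the latent-scale constant π²/3 enters
only the VPC. A σ̂_u at the boundary (≤ 1e-3) collapses the model to plain
logistic regression, which is then refitted directly and flagged.
Separation is detected as any |β_k|·sd(x_k) > 50 and raised as an error.

Inference on fixed effects is Wald throughout; odds-ratio CIs are
exp(β ± 1.96·SE). This deliberately differs from iterative generalised
least squares or quasi-likelihood schemes used by other multilevel software:
under normality IGLS converges to ML, and adaptive quadrature is the
accuracy benchmark for random-intercept logistic likelihoods, so remaining
differences are of the order of estimation error and are covered by the
tolerance bands in the tests.

### Variance decomposition and stratum predictions

* VPC (%) = 100·σ²_u/(σ²_u + σ²_e), with σ²_e replaced by π²/3 ≈ 3.289868
  for logistic models.
* PCV (%) = 100·(σ²_u,null − σ²_u,model)/σ²_u,null. This is the *positive
  reduction* convention; a literal difference-over-null ratio would be
  negative for reductions while reported percentages are conventionally
  positive. Negative PCVs (variance increased) are possible and flagged.
* Empirical-Bayes intercepts: linear û_j = λ_j·(mean raw residual),
  λ_j = σ²_u/(σ²_u + σ²_e/n_j), with conditional (comparative) posterior SD
  √(σ²_u(1−λ_j)); logistic û_j is the posterior mode with Laplace SD from
  the curvature at the mode. Intervals are mode ± 1.96·SD. Both are
  approximations to the full posterior; they are validated against dense
  1-D numerical integration in tests.
* Stratum predictions: the excluding-RE prediction averages member-level
  fixed-part predictions (probability scale per member for logistic, then
  averaged) — well-defined for categorical covariates and faithful to
  per-stratum averaging; the including-RE prediction adds û_j on the linear
  predictor before the link. Excluding-RE CIs are Wald on the stratum-mean
  covariate row using the fixed-effect covariance; including-RE CIs add the
  posterior variance of û_j; the covariance between fixed and random parts
  is ignored (documented approximation). Logistic intervals are built on
  the logit scale around the logit of the averaged probability and
  inverse-linked, guaranteeing [0, 1] and containing the point estimate.
  Empty strata get fixed-part predictions at the decoded behaviour codes
  with confounders at their analysis-set means, flagged as empty.
* Interaction flags: a stratum is flagged when its including-RE and
  excluding-RE 95% CIs are *strictly* disjoint, compared on unrounded
  values (two intervals printing as touching at one decimal can still be
  disjoint). The flag is meaningful for models containing the behaviour
  main effects (Models 2–3): under the null model the two predictions
  differ by construction wherever strata genuinely differ. The rule's error
  rate is not calibrated; flags are reported as indications, not p-values.
* Ranking is ascending by the including-RE point estimate with ties broken
  by key; report tables round BMI to 1 decimal, probabilities to 2 and
  percentages to 2, while all internal comparisons use unrounded values.

### Pipeline

Analyses are stratified by sex; age and TDI are centred at their
sex-specific means computed on the post-exclusion analysis set (the only
choice consistent with sex-stratified models). Exclusions precede stratum
assignment precede fitting, and VPC/PCV are always compared across models
fitted with the same estimation method. Collinearity diagnostics (pairwise
correlations and VIF_k = 1/(1−R²_k), intercept included in each auxiliary
regression) run on the largest requested design. The report bundle is a
pure function of (input table, configuration) — no timestamps — so repeated
runs are byte-identical; a configuration hash provides provenance. A
failure in one (sex, outcome) cell is recorded with its reason and the
other cells proceed.

## Synthetic cohorts

The generator emulates the structure of a large sex-stratified adult cohort:

* Behaviour prevalences per sex default to published descriptive marginals
  (e.g. 11.2% male current smokers, 82.1% of males meeting the activity
  guideline) and are sampled **independently across behaviours** — only
  marginal prevalences are published, so behaviour–behaviour correlation is
  an assumption, not data. An empirical correlation hook is out of scope.
* BMI is additive: intercept (29.82 male / 28.60 female kg/m²) + per-level
  behaviour effects (confounder-adjusted published main effects, e.g.
  −1.08 kg/m² for males meeting the activity guideline) + optional centred
  confounder effects (zero by default — published confounder adjustment
  changed the variance decomposition very little) + a latent per-stratum
  offset (SD `extra_stratum_sd`, default 0) + any injected per-stratum
  interaction offsets + Normal(0, √15.15) residual noise. With the defaults
  the generative model is purely additive, so the ground-truth PCV is 100%.
* Raw questionnaire measures are drawn uniformly within the range consistent
  with each drawn code (e.g. sleep meets → Uniform[7, 9] h) — the simplest
  distribution satisfying the recoding round-trip, which tests verify
  exactly.
* Obesity defaults to the threshold rule (BMI ≥ 30), keeping the linear and
  logistic pipelines coherent on one cohort; the `independent-logit` rule
  instead draws obesity from `logit(π_j) = β0 + u_j` with a user-set latent
  σ_u, used for logistic recovery studies with exactly known truth.
* A single integer seed drives one `numpy.random.default_rng` stream with a
  fixed draw order (per sex: behaviour codes, raw measures, confounders,
  stratum offsets, residuals, latent-logit draws), so cohorts are
  reproducible bit-for-bit.

Under the defaults the implied between-stratum structure lands where
published MAIHDA null models typically sit: null VPC ≈ 4% (linear) and
≈ 7% (logistic) with PCV ≈ 100% after main effects. What passing tests on
these cohorts show is that the *pipeline* recovers known structure — they do
not show that real behaviours are independent, that real effects are exactly
additive, or anything about survey non-response, measurement error or
sampling design, none of which the generator emulates.

## Problem sizes and numerical choices

Simulation-backed tests use cohorts of 50,000–100,000 per sex with 10–20
replicates — large enough that the 48-stratum variance components are
estimated with single-digit-percent Monte-Carlo error in the replicate
means, small enough to keep the full suite in a few minutes. With only 48
level-2 units the sampling SD of σ̂²_u is ≈ √(2/47) ≈ 21% of its value per
replicate; recovery checks therefore compare replicate *means* against
truth.

Numerical limits worth knowing:

* The profiled REML criterion is flat near its optimum at machine-precision
  scale, so re-ordering records or rescaling y by a non-power-of-two moves
  σ̂²_u by O(√ε) ≈ 1e-6 relative. VPC/PCV scale invariance is therefore
  exact only to ~1e-5 in the VPC percent, and fits are order-invariant to
  the same scale; fixed effects are far tighter (~1e-8).
* Quadrature order 15 is the default; estimates move by < 1e-4 between
  orders 7 and 31 in tests, and the optimised log-likelihood is
  non-decreasing in the order beyond 7.
* Degenerate inputs raise rather than return: constant outcomes (zero
  residual variance), singular designs (the collinear columns are named),
  separation in logistic fits, malformed CIs, invalid stratum keys.

## Limitations

* REML/adaptive-GHQ point estimates are not bit-identical to IGLS/MCMC or
  quasi-likelihood implementations; agreement is statistical, not exact.
* Random-intercept interval estimates use conditional SDs and ignore the
  fixed–random covariance; they are approximations, validated only in the
  senses described above.
* No multinomial model for the three-category weight outcome (the two
  binary contrasts are fitted separately), no random slopes, no more than
  two levels, no imputation, no survey weights, no plotting.
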