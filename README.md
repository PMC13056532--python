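# maihda

Multilevel Analysis of Individual Heterogeneity and Discriminatory Accuracy
(MAIHDA) applied to lifestyle behaviours and obesity: a tested, reusable
pipeline for epidemiologists who want to ask how much of the variation in BMI
or obesity risk sits *between* combinations of lifestyle behaviours versus
*between individuals* within those combinations, and whether specific
combinations carry interaction (multiplicative) effects beyond the sum of the
individual behaviours.

## The model

Five behaviours are coded against public-health guidelines — sleep (7–9
h/day), fruit & vegetable intake (≥ 5 portions/day), alcohol (≤ 14
units/week), physical activity (≥ 150 min moderate or ≥ 75 min vigorous per
week) as binary *meets/not-meets*, and smoking as *previous/current/never* —
and combined into 48 strata (2×2×2×2×3), identified by 5-digit keys such as
`01112`. Individuals i are nested in strata j and three two-level
random-intercept models are fitted per sex and outcome:

* **Model 1 (null)** — linear: `bmi_ij = β0 + u_j + e_ij`, with
  `u_j ~ N(0, σ²_u)`, `e_ij ~ N(0, σ²_e)`; logistic:
  `logit(π_j) = β0 + u_j` for obesity vs. normal weight.
* **Model 2 (main effects)** — adds the five behaviour codes as fixed
  effects.
* **Model 3 (adjusted)** — adds confounders (age and Townsend Deprivation
  Index centred at their sex-specific means, ethnicity, employment).

From each model the pipeline computes

* **VPC** `= 100·σ²_u / (σ²_u + σ²_e)` — the share of total variance between
  strata; in logistic models the individual-level component is fixed at the
  latent-scale constant `π²/3 ≈ 3.29`;
* **PCV** `= 100·(σ²_u(null) − σ²_u(model)) / σ²_u(null)` — how much of the
  between-stratum variance the additive main effects absorb;
* **stratum predictions** with and without the empirical-Bayes (shrunken)
  random intercept `û_j = λ_j·(mean residual)`,
  `λ_j = σ²_u/(σ²_u + σ²_e/n_j)`, each with 95% CIs, ranked ascending; a
  stratum whose two intervals are strictly disjoint is flagged as carrying a
  multiplicative (interaction) effect.

Linear models are estimated by profiled REML (ML optional); logistic models
by maximum likelihood with adaptive Gauss–Hermite quadrature over the
stratum random intercept. Because real cohort data of this kind are
access-restricted, the package ships a first-class synthetic cohort
generator whose defaults reproduce published descriptive marginals and
additive behaviour effects, with known ground truth (including injectable
stratum-specific interaction offsets) so that every downstream stage is
testable end to end.

## Worked example

```sh
maihda simulate --seed 1 --out cohort.csv
maihda run --input cohort.csv --outcome bmi --sex male --models 1,2,3 --outdir out
maihda report --bundle out/report.json --format markdown
```

prints (abridged):

```
wrote 20000 records to cohort.csv (truth: cohort.csv.truth.json)
WARNING maihda: model 3 (male, bmi): boundary estimate sigma2_u = 0
report written to out/report.json

## male:bmi
n = 9909, non-empty strata = 48

| model | sigma2_u | VPC % | PCV % |
|---|---|---|---|
| 1 | 0.5495   | 3.68 | 0.00   |
| 2 | 1.9e-12  | 0.00 | 100.00 |
| 3 | 0        | 0.00 | 100.00 |

Model 3 lowest-5 strata: 11112, 10112, 11111, 10111, 11012
Model 3 highest-5 strata: 10000, 01100, 00100, 01000, 00000
Interaction flags: none
```

Reading: in the null model 3.68% of BMI variance lies between the 48
behaviour combinations (VPC). Adding the behaviour main effects absorbs
essentially all of it (PCV 100%, VPC → 0, a boundary estimate flagged in the
log) — exactly what a purely additive generative model should show, and no
stratum is flagged as interactive. The lowest-BMI strata all meet the
physical-activity and sleep guidelines (keys ending `…1x2`/`…1x1` with
first digit 1), the highest meet almost none. The same commands with
`--outcome obesity` run the logistic pipeline on the obesity-vs-normal
contrast.

The equivalent library calls are `generate_cohort`, `recode_behaviours`,
`apply_exclusions`, `assign_strata`, `fit_linear` / `fit_logistic`,
`linear_blups` / `logistic_eb_intercepts`, `predict_strata`, `rank_strata`,
`compute_vpc` / `compute_pcv`, or `run_maihda` for the whole sequence; see
`docs/methods.md` for the statistical details and design choices.

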