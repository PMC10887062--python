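# isdkit

Individual survival distributions (ISDs) for clinical survival cohorts.

Classical survival analysis summarizes a cohort: a Cox model returns one
risk score per patient and one shared baseline curve.  An ISD instead
gives *every patient their own survival curve* S(t|x), queryable at any
future time.  `isdkit` implements the full analysis pattern around this
idea for patient-level tables of the kind produced by pooled
gastric-adenocarcinoma registries (overall-survival time in months, death
indicator, clinical covariates, continuous molecular-subtype scores),
aimed at biostatisticians and computational oncologists who want
per-patient curves, honest calibration assessment, and time-resolved
covariate effects.

## What it implements

**Models** (all producing `SurvivalCurve` objects):

- **MTLR** — multi-task logistic regression: a logistic predictor
  θ_j(x) = w_j·x + b_j at each of m = ⌈√(#uncensored)⌉ quantile-placed
  time points; the probability of death in interval k is
  u_k(x)/Z(x) with u_k = exp(Σ_{j≥k} θ_j(x)).  Censored patients
  contribute the probability of the union of admissible death intervals.
  Not bound by proportional hazards — two patients' curves can cross.
  Ridge-penalized convex fit (L-BFGS, exact gradient, log-sum-exp
  stabilized), λ by inner 5-fold CV; optional temporal-smoothness
  penalty for time-profile analysis.
- **Cox-KP** — Breslow partial likelihood by Newton–Raphson plus the
  Kalbfleisch–Prentice baseline (reduces exactly to Kaplan–Meier at
  β = 0), so the Cox model also yields per-patient curves.
- **CoxEN-KP** — elastic-net-penalized Cox (FISTA + active-set Newton).
- **Weibull AFT** — ln T = μ + γ·x + σW maximum likelihood.

**Evaluation** under event-stratified 5-fold CV: Harrell's concordance
(risk = negative predicted median survival), **1-calibration**
(Hosmer–Lemeshow-type test at anchor times, censoring-adjusted via
within-decile Kaplan–Meier with Greenwood variances), **D-calibration**
(are the S_i(t_i) uniform over probability deciles, censored patients
contributing conditional-uniform fractional mass?), and the IPCW
**integrated Brier score**.

**Interpretation**: per-time-point MTLR weight profiles pooled over CV
folds, influence ranking, bootstrap forest summaries with
Wilcoxon/Benjamini–Hochberg significance, Pearson correlation of MTLR
mean weights against full-data Cox coefficients, and counterfactual
curve pairs (the same patient with one input toggled).

**Synthetic cohorts**: a generator emulating a pooled gastric-cancer
cohort's covariate marginals with a piecewise-exponential event process
whose log-hazard effects can be step functions of time (chemotherapy
protective early then null, TME score protective late, …), plus
closed-form ground-truth survival for every simulated patient.  See
`docs/methods.md` for the model details and the generator's limitations.

## Worked example

```sh
isdkit simulate --n 500 --seed 7 --out cohort.csv --truth truth.csv
isdkit evaluate --cohort cohort.csv --models CoxKP,MTLR --k 5 \
    --cv-seed 1 --lambda-grid 0.25,4.0 --out-dir eval
```

prints

```
simulate: n=500 events=254 censored=0.492 seed=7 -> cohort.csv
evaluate: n=500 events=254 k=5 seed=1
  MTLR: selected penalty 4
  full-data MTLR: m=16 lambda=4 -> mtlr_model.json
```

and writes `eval/table2.csv`, a models-by-metrics table:

```
,CoxKP,MTLR
Concordance,0.608 ± 0.045,0.604 ± 0.025
D-Calibration,0.965,0.185
1-Calibration 10th,0.126,0.148
...
Integrated Brier,0.194 ± 0.018,0.199 ± 0.018
```

Concordance ~0.60 means the models order ~60% of comparable patient
pairs correctly on this cohort (0.5 = chance); the calibration rows are
p-values whose null hypothesis is "the model is calibrated", so values
above 0.05 are good.  Per-patient prediction with a counterfactual
chemotherapy toggle (a 49-year-old untreated Stage II male from the
simulated cohort):

```sh
isdkit predict --model eval/mtlr_model.json --patient patient.csv \
    --times 24,48 --toggle treatment=Yes --out curve.csv
```

```
median survival: 37.62 months
S(24) = 0.5937
S(48) = 0.3051
delta S(24) under toggle: +0.2161
delta S(48) under toggle: +0.0969
median under toggle: 45.07 months
```

The model predicts a 21-point higher 2-year survival probability with
chemotherapy for this patient — consistent with the generator's
protective-early treatment effect — and the benefit shrinks by 4 years
as that effect tapers off.  `isdkit interpret` writes the time-resolved
weight profiles, the bootstrap forest table and the Cox-correlation
scatter behind such statements.

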