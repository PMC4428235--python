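# neoprog

Prognostic survival modelling for locally advanced (stage III) non-small-cell
lung cancer treated with induction chemotherapy, neoadjuvant radiochemotherapy,
and resection. The package is aimed at biostatisticians and clinical
researchers who want to quantify how much histopathologic response to
neoadjuvant therapy — above and beyond pretreatment clinical factors — tells
us about long-term survival, and to build and *honestly* evaluate prognostic
risk groups from such cohorts.

## What it computes

Let `T` be overall survival from the start of induction chemotherapy and `x`
a patient's covariates (clinical factors such as age, sex, cN3 category, and
histopathologic response markers such as pathologic complete remission, pCR).
The analysis chain is:

- **Kaplan-Meier / log-rank machinery** with Greenwood standard errors,
  optional per-subject weights, and a stratified log-rank variant.
- **Cox proportional hazards** `h(t|x) = h0(t) exp(beta' x)` fitted by
  Newton-Raphson on the partial likelihood (Efron or Breslow ties), with
  stepwise backward elimination at `alpha = 0.05`, Schoenfeld-residual and
  covariate-by-time interaction diagnostics, and absolute survival
  `S(t|x) = exp(-Lambda0(t) e^{beta'x})` from the Breslow baseline.
- **Fractional-weight long-term-survivor diagnostics.** A long-term survivor
  lives `>= 36` months. A patient censored earlier contributes with weight
  `w = S(36|x)/S(t_obs|x)` as a long-term and `1-w` as a short-term survivor;
  response markers are then scored by weighted sensitivity, specificity,
  positive likelihood ratio `LR+ = sens/(1-spec)` with 95% CIs, and a
  Cochran-Mantel-Haenszel association test.
- **Risk grouping and cross-validated evaluation.** The prognostic index
  `beta' x` is split at the median into equal high/low risk groups; 10-fold
  cross-validation rebuilds the model (variable selection and threshold
  included) from scratch per fold, and two covariate sets are compared by the
  difference of the log-rank chi-squares of their cross-validated curves,
  with a permutation null.
- **Recursive-partitioning survival tree** using the log-rank test as the
  splitting criterion and the largest 5-year-survival separation for split
  selection.
- **Synthetic cohort generator** reproducing the published cohort's covariate
  marginals, response-marker dependence (CT response and deltaSUVmax versus
  pCR), proportional-hazards effect structure (pCR HR 0.41, cN3 HR 1.52,
  female HR 0.57, age HR 1.02/year on overall survival; pCR HR 0.34 on time
  to progression), and accrual/administrative censoring — so the entire
  pipeline is testable without patient-level data.

## Worked example

```python
from neoprog import (GeneratorConfig, generate_cohort, backward_eliminate,
                     longterm_weights, marker_diagnostics, compare_models)

cohort = generate_cohort(GeneratorConfig(n=157, seed=42))

model = backward_eliminate(cohort, "clinical_plus_path", alpha=0.05,
                           forced=["age_years"])
print(model.summary().round(3))

w = longterm_weights(cohort, model, threshold_months=36)
d = marker_diagnostics(cohort.design_matrix(["pcr"])["pcr"] == 1, w)
print(f"pCR: sens {d.sensitivity:.2f}, spec {d.specificity:.2f}, "
      f"LR+ {d.positive_lr:.2f}")

cmp = compare_models(cohort, "clinical_plus_path", "clinical_only",
                     k=10, seed=7, n_permutations=100)
print(f"delta chi-square {cmp.delta_chi_square:.2f}, p = {cmp.p_value:.3f}")
```

prints (seed 42):

```
                     coef  hazard_ratio  hr_ci_lower  hr_ci_upper     se      p
age_years           0.010         1.010        0.984        1.036  0.013  0.455
female             -0.451         0.637        0.428        0.948  0.203  0.026
cn3                 0.446         1.561        1.027        2.374  0.214  0.037
concurrent_cis_vin -0.766         0.465        0.266        0.814  0.286  0.007
pcr                -3.468         0.031        0.007        0.147  0.790  0.000
ypt0                2.389        10.901        2.477       47.979  0.756  0.002
pCR: sens 0.46, spec 0.82, LR+ 2.61
delta chi-square 11.65, p = 0.000
```

Reading this: on one simulated 157-patient cohort the selection keeps the
true effects (female HR 0.64, cN3 HR 1.56, and a protective pCR) plus, as
expected at this sample size, some chance structure — the ypT0 marker,
nearly collinear with pCR, enters with an offsetting coefficient, and one
treatment variable survives selection by luck. pCR is a specific but
insensitive marker of long-term survival (weighted specificity 0.82,
sensitivity 0.46), and adding the histopathologic markers separates
cross-validated risk groups significantly better than preoperative factors
alone (permutation p below the 1/100 resolution).

The same analysis is available from the shell:

```sh
neoprog synth generate --n 157 --seed 42 --out cohort.csv
neoprog cohort validate cohort.csv
neoprog fit cox --cohort cohort.csv --covariates full --out fit.json
neoprog markers table2 --cohort cohort.csv --weight-model fit.json --out table2.csv
neoprog riskmodel cv-compare --cohort cohort.csv --k 10 --seed 7 \
    --permutations 100 --out cv.json
neoprog rpa grow --cohort cohort.csv --out tree.json
neoprog run-all --n 157 --seed 42 --out-dir out/   # everything, with manifest
```

## Layout

```
src/neoprog/
  cohort.py      data model, CSV I/O, covariate design
  synthetic.py   calibrated synthetic cohort generator + printed-table fixtures
  survival.py    KM, log-rank, Cox, backward elimination, PH diagnostics
  longterm.py    fractional-weight long-term-survivor marker diagnostics
  riskmodel.py   prognostic index, median split, cross-validated comparison
  rpa.py         log-rank recursive-partitioning survival tree
  pipeline.py    end-to-end orchestration with manifest
  cli.py         `neoprog` command-line interface
docs/methods.md  model assumptions, calibration, and design choices
```
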