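# Methods

This note documents the statistical models the package implements, the
synthetic cohort that exercises them, the numerical choices, and the
limitations a user should know before trusting a number.

## Cohort and time scale

One row per resected patient. Both outcomes — overall survival (OS) and time
to progression (TTP) — are measured in months from the start of induction
chemotherapy. Every patient has histopathologically proven mediastinal nodal
involvement at staging, so the clinical nodal category is restricted to
{cN2, cN3} and only the cN3 indicator enters model designs (a cN2 indicator
would be its complement, and a constant shift is inestimable in a partial
likelihood). The design also carries a neutral binary `stage_flag` whose
defining rule is configurable (default: cT4 or cN3, i.e. a IIIB-type
indicator); it exists to preserve the dimensionality of the historical
covariate list, whose stage entry is ambiguous, without asserting a
clinical meaning. Validation is strict complete-case: any missing required
field rejects the row at read time; the PET-derived SUV ratio is the only
optional field.

## Survival machinery

*Kaplan-Meier* is the standard product-limit estimator with Greenwood
variance; optional non-negative per-subject weights replace counts by weight
totals in both. Curves are right-continuous steps; evaluation beyond the last
event time carries the last value forward.

*Log-rank* uses the hypergeometric observed-minus-expected form with the
`(n-1)`-denominator variance; the K-group statistic inverts the covariance of
the first K-1 groups (pseudo-inverse for safety). A stratified variant
accumulates the O-E vectors and covariances over strata.

*Cox fitting* maximises the partial likelihood by Newton-Raphson with
step-halving, from `beta = 0` on mean-centred columns, converging when the
score max-norm falls below 1e-6 and the log-likelihood change below 1e-9
(at most 50 iterations). Tied event times use the Efron correction by
default; Breslow is available for fits in the style of older software.
Constant or collinear design columns are an error at this level (callers
that face arbitrary subsamples — cross-validation folds, the CLI — pre-drop
degenerate columns, earliest declared column wins). A coefficient exceeding
15 in absolute value flags a likely monotone likelihood (complete
separation) and marks the fit non-converged. The baseline cumulative hazard
is the Breslow estimator at the fitted coefficients, also under Efron ties
(the difference is third-order for the weight model's conditional survival
ratios); absolute survival is `S(t|x) = exp(-Lambda0(t) e^{beta'x})`.

*Backward elimination* repeatedly removes the least significant non-forced
covariate with `p >= alpha` and refits; p-values are Wald by default, with a
likelihood-ratio drop test as an option (which of the two the original
analysis used is not recorded; both are provided). Ties in p are broken
toward the covariate declared later, making the procedure deterministic.
`alpha >= 1` is the boundary case and keeps the full model. An empty final
model is legal when nothing is forced; the removal history is attached to
the returned fit.

*Proportional-hazards diagnostics* are two per-covariate checks: the
correlation of Schoenfeld residuals with the rank order of failure times
(t-test p), and a Wald test of an added covariate-by-`g(t)` interaction
(`g` = identity, centred at the mean event time). The interaction fit uses a
per-risk-set accumulation (quadratic in n) because the interaction covariate
changes at every event time; it is intended for the small reduced models
diagnostics are run on, not for 20-covariate designs at large n.

## Long-term-survivor weights and marker diagnostics

Long-term survival means living at least `threshold = 36` months. Deceased
patients and patients followed past the threshold classify deterministically
(weight 0 or 1). A patient censored alive at `t < 36` gets the conditional
probability of reaching the threshold under a fitted Cox model,

    w = S(36 | x) / S(t | x),

as their long-term weight, `1 - w` short-term. The default weight model is
the backward-selected clinico-pathologic OS model with age forced (the most
informative model available); this is configurable because the original
analysis does not record which covariates its weight model contained.

A binary marker's weighted 2x2 table gives sensitivity `= (long-term weight
among marker-positives)/(total long-term weight)`, specificity analogously
on the short-term side, and `LR+ = sens/(1-spec)`. Confidence intervals are
Wald on the probability scale for sensitivity and specificity (effective
denominators = weighted totals) and the log-method for LR+, matching the
interval style of the published table. The association test is
Cochran-Mantel-Haenszel, implemented for K strata with (possibly fractional)
weighted cells entering directly; with one stratum it equals `(N-1)/N` times
the Pearson chi-square. With all-integer weights every statistic reduces
exactly to the count formulas — this is how the published table rows that
are reproducible from integer counts are verified. The published pCR and
pCR-T rows are *not* reproducible from integer counts (their printed LR+
differs from the count-based value), which is consistent with fractional
weights having entered those cells; the exact weighted cells are
unrecoverable and are not asserted.

For binary classifications the Spearman rank correlation equals the phi
coefficient of the 2x2 table; its p-value uses the t approximation with
n-2 degrees of freedom. Metabolic response classifies a patient as responder
iff the post/pre SUVmax ratio is strictly below 0.3; missing ratios are
excluded from subgroup analyses.

## Risk grouping and cross-validated comparison

The prognostic index is `beta' x` — the log of the patient's hazard factor.
Groups split at the median: strictly above = high risk, at or below = low
risk, so equal sizes hold up to ties and a 157-patient cohort splits 78/79.
Age is forced into risk models as a continuous term so the index is
continuous and the median split well defined even when selection removes
everything else.

Cross-validation uses a seeded uniform random partition into k near-equal
folds. For each fold the entire model-building recipe — degenerate-column
pre-drop, backward elimination, coefficient fit, and the median threshold —
is recomputed on the other k-1 folds only and applied to the held-out
patients; retained covariate sets may differ between folds. The held-out
threshold is the *training-set* median: using anything involving the test
fold would leak outcome information.

Two covariate sets are compared on a shared fold partition by
`delta = chi2_A - chi2_B`, the difference of the log-rank statistics of the
two cross-validated groupings. The null distribution of `delta` is not a
standard chi-square (the two statistics are dependent), so the package uses
a permutation null: the (time, event) pairs are permuted against the
covariate rows, both cross-validations are re-run in full, and the p-value
is the fraction of permuted deltas at least as large as observed. Fewer
than 20 permutations is refused as unstable. On the full ~25-covariate
design at n = 157 one permutation costs roughly two seconds of CPU, so the
pipeline default is 100 permutations (p-value resolution 0.01).

## Recursive-partitioning survival tree

At each node, every dichotomic candidate is scored by the two-sample
log-rank test. Splits require raw `p < alpha` (no multiplicity correction
across candidates, matching the published rule; a Bonferroni switch exists)
and both children at least `min_child = 7` patients. Among admissible
candidates the one maximising |S5y(child1) - S5y(child0)| wins; ties go to
the larger log-rank statistic, then the earlier declared candidate. Growth
stops below `min_node = 20` patients or at depth 4 — defaults chosen as
consistent with the granularity a ~157-patient tree supports, since the
original analysis does not state its stopping rule. Nodes record
Kaplan-Meier survival at 36 and 60 months with Greenwood SEs; a node whose
follow-up does not reach 60 months carries the last KM value forward and is
flagged as extrapolated. Continuous covariates are not candidates by
default (the rule is defined for dichotomic factors).

## Synthetic cohort generator

The generator defines the study conditions all simulation-based tests run
under; it emulates the published cohort, not any individual patient.

**Covariates.** Marginals are the published patient-characteristics
frequencies (60% male; cT/cN sampled from the printed four-cell joint since
the full joint is unpublished; 51% hyperfractionated-accelerated
radiotherapy; etc.). The split of the lumped cT1-3 cell into cT1/2/3
(10/45/45%), the Charlson distribution (Poisson, mean 0.8), the count of
positive mediastinal nodes (1 + Poisson(0.8)), and the age distribution
(normal 58.5 +/- 8.5 truncated to 34-74, matching the printed median and
range) are unpublished and were chosen once as realistic for this setting.

**Response hierarchy.** Regression grade is sampled first from the printed
four-level frequencies; ypT0 is its top level; pCR occurs in 41/46 of ypT0
patients; nodal clearance is certain under pCR and has probability 44/116
otherwise. This makes the logical invariants (pCR implies ypT0 and ypN0)
true by construction and reproduces the printed marker totals. CT response
is drawn conditional on pCR with the odds of the printed 2x2 table
(producing the published phi of about 0.21), and the PET subsample with its
deltaSUVmax response likewise (phi about 0.28).

**Outcomes.** OS event times follow a proportional-hazards model with true
log-hazard-ratios pCR ln 0.41, cN3 ln 1.52, female ln 0.57, and age
ln 1.02 per year (centred at 59). The baseline is Weibull with rate and
shape jointly least-squares calibrated — deterministically, via a fixed
internal covariate sample — so the *marginal* survival of the default mix
passes through the published points S(24)=0.56, S(36)=0.46, S(60)=0.36. A
single-rate exponential baseline is exposed as an option but cannot reach
all three points under this covariate mix (its marginal hazard decays too
slowly; the calibrated fit misses S(60) by about five percentage points),
which is why the calibrated Weibull is the default. The latent progression
time is conditionally independent of the death time given covariates, with
pCR log-HR ln 0.34 and an exponential baseline of rate 0.035/month (median
TTP near 20 months for a reference patient — unpublished, chosen once as
realistic); observed TTP is censored by death and by the administrative
cutoff, so TTP never exceeds OS and a cause-specific Cox fit recovers the
generating TTP effect. Censoring is uniform accrual over 144 months plus a
fixed 15-month administrative window to data cutoff, mirroring the cohort's
accrual and survival-update dates; there is no loss to follow-up.

**What passing tests do and do not show.** The generator satisfies the
proportional-hazards assumption exactly, has no unmeasured confounding, no
missingness beyond the PET subsample, no era effects, and purely
administrative censoring. Parameter-recovery and calibration results
therefore validate the *implementation*, not the clinical model; real
cohorts can violate each of these assumptions.

## Problem sizes used in the checks

Simulation-based checks use sizes chosen for the tolerance being asserted:
hazard-ratio recovery uses 50 cohorts of n = 5000 (Monte-Carlo SE of the
geometric-mean HR well under 0.01 against a +/-0.03 band); the marginal
survival calibration uses one cohort of n = 20000 (binomial SE about 0.4
percentage points against a +/-1.5-point band); elimination, cross-validation
calibration/power, and tree-structure rates use 10-40 replicates at
n = 150-2000 with assertion bands set from the corresponding binomial
variability. The cross-validation type-I and power checks run with k = 5
folds, reduced covariate sets, and 39 permutations, which keeps the
permutation test's rejection rule exact at the 0.05 level.

## Known limitations

- No frailty terms, left truncation, competing risks, or penalised
  regression; TTP is handled as a cause-specific hazard, not a cumulative
  incidence.
- The weighted CMH test treats fractional weighted cells as if they were
  counts; its null distribution is approximate under heavy weighting.
- The permutation null for the model comparison conditions on the fold
  partition; a different fold seed gives a (slightly) different statistic.
- The time-varying-coefficient diagnostic is quadratic in the number of
  subjects and meant for reduced models.
- Divergent fits (complete separation) are flagged, not penalised away;
  backward elimination usually removes such covariates early because their
  Wald p-values are near 1.
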