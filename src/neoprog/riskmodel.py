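"""Prognostic-index risk grouping and cross-validated model evaluation.

The prognostic index of a patient is the inner product of the Cox regression
coefficients with the patient's covariate values -- the log of the factor the
patient contributes to the hazard. Splitting at the in-sample median yields
equally sized high- and low-risk groups whose Kaplan-Meier curves are
compared by the log-rank test.

Predictive (rather than descriptive) separation is measured by k-fold
cross-validation: each fold's risk labels come from a model built from
scratch -- backward elimination and median threshold included -- on the
other folds only, so no patient's label ever depends on their own outcome.
Two candidate covariate sets (with and without the histopathologic response
markers) are compared by the difference of the log-rank chi-squares of their
cross-validated curves; its null distribution is obtained by permuting the
outcome vector against the covariate rows and re-running both
cross-validations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import (CoxFit, LogRankResult, SurvivalCurve, backward_eliminate_arrays,
                       km_estimate, logrank_test)

__all__ = [
    "RiskGrouping",
    "CrossValidatedGrouping",
    "CVComparison",
    "prognostic_index",
    "median_split",
    "build_risk_model",
    "crossval_km",
    "compare_models",
]


# ---------------------------------------------------------------------------
# Prognostic index and median split
# ---------------------------------------------------------------------------

def prognostic_index(fit: CoxFit, cohort) -> np.ndarray:
    """Per-patient index beta' x under the fitted model (empty model -> 0)."""
    if not fit.covariate_names:
        return np.zeros(len(cohort))
    X = cohort.design_matrix(fit.covariate_names)
    return X.to_numpy(float) @ fit.coefficients


@dataclass
class RiskGrouping:
    """Median split of the prognostic index into high/low risk groups."""

    prognostic_index: np.ndarray
    group: np.ndarray            # 'high' / 'low' per patient
    threshold: float
    degenerate: bool = False
    km_high: SurvivalCurve | None = None
    km_low: SurvivalCurve | None = None
    logrank: LogRankResult | None = None

    def attach_outcome(self, times, events) -> "RiskGrouping":
        """Compute per-group KM curves and the log-rank test."""
        times = np.asarray(times, float)
        events = np.asarray(events, bool)
        hi = self.group == "high"
        if self.degenerate or hi.all() or (~hi).all():
            self.degenerate = True
            return self
        self.km_high = km_estimate(times[hi], events[hi])
        self.km_low = km_estimate(times[~hi], events[~hi])
        self.logrank = logrank_test(times, events, self.group)
        return self


def median_split(indices, threshold: float | None = None) -> RiskGrouping:
    """Assign 'high' to indices strictly above the (or a given) threshold.

    Default threshold is the in-sample median; patients exactly at the
    threshold go to the low-risk group, so equal group sizes hold up to ties.
    A constant index vector yields a degenerate single-group result.
    """
    idx = np.asarray(indices, dtype=float)
    if len(idx) < 2 and threshold is None:
        raise ValueError("median split requires at least two patients")
    thr = float(np.median(idx)) if threshold is None else float(threshold)
    group = np.where(idx > thr, "high", "low").astype(object)
    degenerate = bool(np.all(group == group[0]))
    return RiskGrouping(idx, group, thr, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Degenerate-column handling for small training sets
# ---------------------------------------------------------------------------

def _usable_columns(Xdf: pd.DataFrame, forced=()) -> tuple[pd.DataFrame, list]:
    """Drop constant columns, then later columns linearly dependent on
    earlier ones (declared order wins), so the partial likelihood is
    estimable on any training subsample. Returns (frame, dropped names)."""
    X = Xdf.to_numpy(float)
    names = list(Xdf.columns)
    dropped = []
    keep_idx: list[int] = []
    Q: list[np.ndarray] = []
    for j, name in enumerate(names):
        col = X[:, j]
        if np.std(col) == 0:
            if name in forced:
                raise ValueError(f"forced covariate '{name}' is constant")
            dropped.append(name)
            continue
        v = col - col.mean()
        for q in Q:
            v = v - (v @ q) * q
        norm = np.linalg.norm(v)
        if norm < 1e-8 * np.linalg.norm(col - col.mean()):
            if name in forced:
                raise ValueError(f"forced covariate '{name}' is collinear")
            dropped.append(name)
            continue
        Q.append(v / norm)
        keep_idx.append(j)
    return Xdf.iloc[:, keep_idx], dropped


# ---------------------------------------------------------------------------
# In-sample risk model
# ---------------------------------------------------------------------------

def build_risk_model(cohort, covariate_set="clinical_plus_path", force_age: bool = True,
                     alpha: float = 0.05, outcome: str = "os",
                     ties: str = "efron") -> tuple[CoxFit, RiskGrouping]:
    """Backward-selected Cox model plus median-split risk grouping.

    ``covariate_set`` is a named set or an explicit list; with ``force_age``
    the continuous age term is kept in the model regardless of significance
    (it may also be the only covariate), giving a continuous prognostic
    index.
    """
    if isinstance(covariate_set, str):
        names = list(cohort.design_matrix(covariate_set).columns)
    else:
        names = list(covariate_set)
    forced = []
    if force_age:
        if "age_years" not in names:
            names = ["age_years"] + names
        forced = ["age_years"]
    Xdf = cohort.design_matrix(names)
    t, e = cohort.outcome(outcome)
    Xdf, dropped = _usable_columns(Xdf, forced)
    fit = backward_eliminate_arrays(t, e, Xdf, alpha=alpha, forced=forced, ties=ties)
    if dropped:
        fit.warnings.append(f"degenerate covariates excluded before elimination: {dropped}")
    grouping = median_split(prognostic_index(fit, cohort)).attach_outcome(t, e)
    return fit, grouping


# ---------------------------------------------------------------------------
# Cross-validated Kaplan-Meier evaluation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidatedGrouping:
    """Pooled out-of-fold risk labels and their survival separation."""

    group: np.ndarray                # 'high'/'low', assigned out of fold
    fold: np.ndarray                 # fold id per patient
    retained: list                   # per fold: covariates kept by elimination
    thresholds: list                 # per fold: training-median threshold
    km_high: SurvivalCurve | None
    km_low: SurvivalCurve | None
    logrank: LogRankResult | None
    degenerate: bool

    @property
    def chi_square(self) -> float:
        return 0.0 if self.logrank is None else self.logrank.chi_square


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    for i, block in enumerate(np.array_split(perm, k)):
        fold[block] = i
    return fold


def _crossval_core(t, e, Xdf: pd.DataFrame, k: int, fold: np.ndarray,
                   alpha: float, forced, ties: str) -> CrossValidatedGrouping:
    n = len(t)
    group = np.empty(n, dtype=object)
    retained, thresholds = [], []
    for i in range(k):
        test = fold == i
        train = ~test
        if not np.any(e[train]):
            raise ValueError(f"training complement of fold {i} contains no events")
        Xtr, _dropped = _usable_columns(Xdf.loc[train], forced)
        fit = backward_eliminate_arrays(t[train], e[train], Xtr, alpha=alpha,
                                        forced=forced, ties=ties)
        cols = fit.covariate_names
        idx_train = (Xdf.loc[train, cols].to_numpy(float) @ fit.coefficients
                     if cols else np.zeros(int(train.sum())))
        thr = float(np.median(idx_train))
        idx_test = (Xdf.loc[test, cols].to_numpy(float) @ fit.coefficients
                    if cols else np.zeros(int(test.sum())))
        group[test] = np.where(idx_test > thr, "high", "low")
        retained.append(list(cols))
        thresholds.append(thr)
    hi = group == "high"
    if hi.all() or (~hi).all():
        return CrossValidatedGrouping(group, fold, retained, thresholds,
                                      None, None, None, degenerate=True)
    return CrossValidatedGrouping(
        group, fold, retained, thresholds,
        km_estimate(t[hi], e[hi]), km_estimate(t[~hi], e[~hi]),
        logrank_test(t, e, group), degenerate=False)


def crossval_km(cohort, covariate_set="clinical_plus_path", k: int = 10,
                seed: int = 0, alpha: float = 0.05, force_age: bool = True,
                outcome: str = "os", ties: str = "efron",
                fold: np.ndarray | None = None) -> CrossValidatedGrouping:
    """k-fold cross-validated risk labels, KM curves, and log-rank statistic.

    Folds are a seeded uniform random partition into k near-equal blocks
    (or an explicit per-patient ``fold`` assignment in 0..k-1). Within each
    fold loop the model -- variable selection and the median threshold -- is
    rebuilt on the training complement only and applied to the held-out
    patients, so each label comes from a model never trained on that
    patient. A fold whose selection retains nothing falls back to the forced
    age term.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(cohort):
        raise ValueError("more folds than patients")
    if isinstance(covariate_set, str):
        names = list(cohort.design_matrix(covariate_set).columns)
    else:
        names = list(covariate_set)
    forced = []
    if force_age:
        if "age_years" not in names:
            names = ["age_years"] + names
        forced = ["age_years"]
    Xdf = cohort.design_matrix(names)
    t, e = cohort.outcome(outcome)
    if fold is None:
        fold = _fold_assignment(len(cohort), k, np.random.default_rng(seed))
    else:
        fold = np.asarray(fold, dtype=int)
        if len(fold) != len(cohort) or set(np.unique(fold)) - set(range(k)):
            raise ValueError("fold assignment must map every patient to 0..k-1")
    return _crossval_core(t, e, Xdf, k, fold, alpha, forced, ties)


# ---------------------------------------------------------------------------
# Difference-of-log-rank-statistics model comparison
# ---------------------------------------------------------------------------

@dataclass
class CVComparison:
    """Cross-validated comparison of two covariate sets on shared folds."""

    cv_a: CrossValidatedGrouping
    cv_b: CrossValidatedGrouping
    chi_square_a: float
    chi_square_b: float
    delta_chi_square: float
    p_value: float
    n_permutations: int
    perm_deltas: np.ndarray = field(repr=False, default=None)


def compare_models(cohort, set_a="clinical_plus_path", set_b="clinical_only",
                   k: int = 10, seed: int = 0, n_permutations: int = 200,
                   alpha: float = 0.05, force_age: bool = True,
                   outcome: str = "os", ties: str = "efron") -> CVComparison:
    """Test whether covariate set A separates cross-validated risk groups
    better than set B.

    The statistic is the difference of the log-rank chi-squares of the two
    cross-validated groupings, computed on a shared fold partition. Its null
    distribution comes from permuting the outcome pairs (time, event) against
    the covariate rows and re-running both cross-validations; the p-value is
    the fraction of permuted differences at least as large as observed.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations < 20 gives an unstable permutation p-value")

    def prep(cset):
        names = (list(cohort.design_matrix(cset).columns)
                 if isinstance(cset, str) else list(cset))
        forced = []
        if force_age:
            if "age_years" not in names:
                names = ["age_years"] + names
            forced = ["age_years"]
        return cohort.design_matrix(names), forced

    Xa, forced_a = prep(set_a)
    Xb, forced_b = prep(set_b)
    t, e = cohort.outcome(outcome)
    n = len(cohort)
    rng = np.random.default_rng(seed)
    fold = _fold_assignment(n, k, rng)

    cv_a = _crossval_core(t, e, Xa, k, fold, alpha, forced_a, ties)
    cv_b = _crossval_core(t, e, Xb, k, fold, alpha, forced_b, ties)
    delta = cv_a.chi_square - cv_b.chi_square

    deltas = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        tp, ep = t[perm], e[perm]
        pa = _crossval_core(tp, ep, Xa, k, fold, alpha, forced_a, ties)
        pb = _crossval_core(tp, ep, Xb, k, fold, alpha, forced_b, ties)
        deltas[b] = pa.chi_square - pb.chi_square
    p = float(np.mean(deltas >= delta))
    return CVComparison(cv_a, cv_b, cv_a.chi_square, cv_b.chi_square,
                        float(delta), p, n_permutations, deltas)
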