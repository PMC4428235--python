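"""Nonparametric and semiparametric survival machinery.

Kaplan-Meier product-limit estimation with Greenwood standard errors
(optionally with per-subject weights), the K-sample log-rank test, Cox
proportional-hazards fitting by Newton-Raphson on the partial likelihood
(Efron or Breslow handling of tied event times), stepwise backward variable
elimination, proportional-hazards diagnostics (Schoenfeld-residual rank
correlation and a covariate-by-time interaction Wald test), and absolute
survival prediction from the Breslow baseline cumulative hazard.

Times are months from the start of induction chemotherapy throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "CoxFit",
    "PHDiagnostics",
    "km_estimate",
    "logrank_test",
    "stratified_logrank_test",
    "fit_cox",
    "fit_cox_arrays",
    "backward_eliminate",
    "backward_eliminate_arrays",
    "ph_diagnostics",
    "baseline_survival",
]

_Z975 = 1.959963984540054

# Newton-Raphson controls: convergence when the score's max-norm and the
# log-likelihood change both fall below tolerance; step-halving on overshoot.
_MAX_ITER = 50
_SCORE_TOL = 1e-6
_LOGLIK_TOL = 1e-9
_MAX_HALVINGS = 30
_DIVERGENCE_BOUND = 15.0  # |beta| beyond this flags monotone likelihood


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray  # sorted distinct times with >=1 event
    survival: np.ndarray     # S(t) just after each event time
    greenwood_se: np.ndarray
    at_risk: np.ndarray      # (weighted) risk-set size at each event time
    n_events: np.ndarray     # (weighted) events at each event time
    n: int = 0
    all_censored: bool = False

    def at(self, t) -> np.ndarray | float:
        """S(t); S(0)=1, right-continuous steps at event times."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival evaluated at negative time")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        s = np.where(idx < 0, 1.0, np.concatenate(([1.0], self.survival))[idx + 1])
        return float(s) if s.ndim == 0 else s

    def se_at(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival evaluated at negative time")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        se = np.where(idx < 0, 0.0, np.concatenate(([0.0], self.greenwood_se))[idx + 1])
        return float(se) if se.ndim == 0 else se


def km_estimate(times, events, weights=None) -> SurvivalCurve:
    """Kaplan-Meier estimate with Greenwood variance.

    ``weights`` are optional non-negative per-subject weights (default 1);
    weighted risk-set and event totals replace counts in both the
    product-limit and the Greenwood sum.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be equal-length 1-d arrays")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    if weights is None:
        w = np.ones_like(t)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != t.shape:
            raise ValueError("weights must match times in length")
        if np.any(w < 0):
            raise ValueError("negative weight")
    n = len(t)
    if not np.any(e & (w > 0)):
        return SurvivalCurve(np.empty(0), np.empty(0), np.empty(0), np.empty(0),
                             np.empty(0), n=n, all_censored=True)

    order = np.argsort(t, kind="stable")
    t, e, w = t[order], e[order], w[order]
    ut = np.unique(t[e & (w > 0)])
    # weighted at-risk and event totals at each distinct event time
    first_idx = np.searchsorted(t, ut, side="left")
    w_suffix = np.concatenate((np.cumsum(w[::-1])[::-1], [0.0]))
    at_risk = w_suffix[first_idx]
    ew = np.where(e, w, 0.0)
    d = np.zeros(len(ut))
    pos = np.searchsorted(ut, t[e])
    np.add.at(d, pos, w[e])
    frac = d / at_risk
    surv = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), 0.0)
    var = surv**2 * np.cumsum(terms)
    return SurvivalCurve(ut, surv, np.sqrt(var), at_risk, d, n=n)


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    group_sizes: dict

    observed: np.ndarray | None = None
    expected: np.ndarray | None = None


def _logrank_oev(t, e, gidx, K):
    """Observed, expected, and hypergeometric covariance for K groups."""
    ut = np.unique(t[e])
    m = len(ut)
    if m == 0:
        return np.zeros(K), np.zeros(K), np.zeros((K, K))
    n_gk = np.empty((K, m))
    d_gk = np.zeros((K, m))
    for k in range(K):
        tk = np.sort(t[gidx == k])
        n_gk[k] = len(tk) - np.searchsorted(tk, ut, side="left")
        te = t[(gidx == k) & e]
        np.add.at(d_gk[k], np.searchsorted(ut, te), 1.0)
    n_k = n_gk.sum(axis=0)
    d_k = d_gk.sum(axis=0)
    O = d_gk.sum(axis=1)
    E = (n_gk * (d_k / n_k)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_k = np.where(n_k > 1, d_k * (n_k - d_k) / (n_k - 1), 0.0)
    P = n_gk / n_k
    V = np.einsum("m,im,jm->ij", c_k, P, -P)
    V[np.diag_indices(K)] += (c_k * P).sum(axis=1)
    return O, E, V


def _oev_to_result(O, E, V, K, labels, sizes) -> LogRankResult:
    z = (O - E)[:-1]
    Vr = V[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(Vr) @ z) if Vr.size else 0.0
    chi2 = max(chi2, 0.0)
    df = K - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2, df, p, dict(zip(labels, sizes)), O, E)


def logrank_test(times, events, group_labels) -> LogRankResult:
    """K-sample log-rank test (hypergeometric observed-minus-expected form)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group_labels)
    if not (len(t) == len(e) == len(g)):
        raise ValueError("times, events and group_labels must have equal length")
    labels, gidx = np.unique(g, return_inverse=True)
    K = len(labels)
    if K < 2:
        raise ValueError("log-rank test requires at least two groups")
    sizes = np.bincount(gidx, minlength=K)
    if np.any(sizes == 0):
        raise ValueError("empty group")
    O, E, V = _logrank_oev(t, e, gidx, K)
    return _oev_to_result(O, E, V, K, labels.tolist(), sizes.tolist())


def stratified_logrank_test(times, events, group_labels, strata) -> LogRankResult:
    """Log-rank test of ``group_labels`` stratified over ``strata``.

    Observed-minus-expected vectors and their covariances accumulate over
    strata, so the comparison is adjusted for the stratum variable. Strata
    without events or without group contrast contribute nothing.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group_labels)
    s = np.asarray(strata)
    if not (len(t) == len(e) == len(g) == len(s)):
        raise ValueError("all inputs must have equal length")
    labels, gidx = np.unique(g, return_inverse=True)
    K = len(labels)
    if K < 2:
        raise ValueError("log-rank test requires at least two groups")
    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    for lev in np.unique(s):
        mask = s == lev
        Ok, Ek, Vk = _logrank_oev(t[mask], e[mask], gidx[mask], K)
        O += Ok
        E += Ek
        V += Vk
    sizes = np.bincount(gidx, minlength=K)
    return _oev_to_result(O, E, V, K, labels.tolist(), sizes.tolist())


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Fitted Cox model: coefficients, covariance, Wald summaries, and the
    Breslow baseline cumulative hazard evaluated at the event times."""

    covariate_names: list
    coefficients: np.ndarray
    covariance: np.ndarray
    hazard_ratios: np.ndarray
    hr_ci_lower: np.ndarray
    hr_ci_upper: np.ndarray
    wald_p: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    converged: bool
    n: int
    n_events: int
    ties: str
    warnings: list = field(default_factory=list)
    elimination_trace: list | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients,
            "hazard_ratio": self.hazard_ratios,
            "hr_ci_lower": self.hr_ci_lower,
            "hr_ci_upper": self.hr_ci_upper,
            "se": self.se,
            "p": self.wald_p,
        }, index=self.covariate_names)


def _risk_structure(t, e, X, ties):
    """Precompute sorted arrays and tie groupings for the partial likelihood."""
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    ut = np.unique(t[e])
    first_idx = np.searchsorted(t, ut, side="left")  # start of each risk set
    # event rows grouped by unique event time (contiguous after the sort)
    ev_rows = np.flatnonzero(e)
    ev_t = t[ev_rows]
    grp = np.searchsorted(ut, ev_t)
    d = np.bincount(grp, minlength=len(ut)).astype(float)
    starts = np.searchsorted(grp, np.arange(len(ut)))
    return t, e, X, ut, first_idx, ev_rows, d, starts


def _pl_derivatives(beta, t, e, X, ut, first_idx, ev_rows, d, starts, ties):
    """Partial log-likelihood, score, and Hessian (Efron or Breslow ties)."""
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)
    S0suf = np.concatenate((np.cumsum(w[::-1])[::-1], [0.0]))
    S1suf = np.concatenate((np.cumsum(wX[::-1], axis=0)[::-1], np.zeros((1, p))))
    S2suf = np.concatenate((np.cumsum(wXX[::-1], axis=0)[::-1], np.zeros((1, p, p))))
    S0 = S0suf[first_idx]
    S1 = S1suf[first_idx]
    S2 = S2suf[first_idx]

    # sums of w, wX, wXX over tied events at each unique event time
    m = len(ut)
    edges = np.concatenate((starts, [len(ev_rows)]))
    wE = w[ev_rows]
    s0d = np.add.reduceat(wE, edges[:-1]) if m else np.empty(0)
    s1d = np.add.reduceat(wX[ev_rows], edges[:-1], axis=0) if m else np.empty((0, p))
    s2d = np.add.reduceat(wXX[ev_rows], edges[:-1], axis=0) if m else np.empty((0, p, p))

    ll = float(eta[ev_rows].sum())
    grad = X[ev_rows].sum(axis=0)
    hess = np.zeros((p, p))
    dmax = int(d.max()) if m else 0
    for l in range(dmax):
        active = d > l
        c = (l / d[active]) if ties == "efron" else np.zeros(int(active.sum()))
        denom = S0[active] - c * s0d[active]
        num1 = S1[active] - c[:, None] * s1d[active]
        num2 = S2[active] - c[:, None, None] * s2d[active]
        ll -= float(np.log(denom).sum())
        r1 = num1 / denom[:, None]
        grad -= r1.sum(axis=0)
        hess -= np.einsum("kij,k->ij", num2, 1.0 / denom) - np.einsum("ki,kj->ij", r1, r1)
    return ll, grad, hess


def _null_loglik(t, e, X, ut, first_idx, ev_rows, d, starts, ties):
    p = X.shape[1]
    ll, _, _ = _pl_derivatives(np.zeros(p), t, e, X, ut, first_idx, ev_rows, d, starts, ties)
    return ll


def fit_cox_arrays(times, events, X, names=None, ties="efron") -> CoxFit:
    """Fit a Cox model from raw arrays; see :func:`fit_cox` for the cohort API."""
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if len(t) != n or len(e) != n:
        raise ValueError("times, events and design matrix must have equal length")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    n_events = int(e.sum())
    if n_events < 1:
        raise ValueError("Cox fit requires at least one event")

    if p > 0:
        sd = X.std(axis=0)
        for j in np.flatnonzero(sd == 0):
            raise ValueError(f"covariate '{names[j]}' is constant")
        if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
            raise ValueError(f"design matrix is rank deficient for covariates {names}")

    warnings: list = []
    if p == 0:
        beta = np.empty(0)
        cov = np.empty((0, 0))
        struct = _risk_structure(t, e, np.zeros((n, 1)), ties)
        ll0 = _null_loglik(*struct[:3], *struct[3:], ties)
        ll = ll0
        converged = True
    else:
        # centering improves conditioning; coefficients are unaffected
        xbar = X.mean(axis=0)
        Xc = X - xbar
        struct = _risk_structure(t, e, Xc, ties)
        ts, es, Xs, ut, first_idx, ev_rows, dd, starts = struct
        beta = np.zeros(p)
        ll, grad, hess = _pl_derivatives(beta, ts, es, Xs, ut, first_idx, ev_rows, dd, starts, ties)
        ll0 = ll
        converged = False
        for _ in range(_MAX_ITER):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            scale = 1.0
            for _h in range(_MAX_HALVINGS):
                cand = beta + scale * step
                ll_new, g_new, h_new = _pl_derivatives(
                    cand, ts, es, Xs, ut, first_idx, ev_rows, dd, starts, ties)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            delta_ll = ll_new - ll
            beta, ll, grad, hess = cand, ll_new, g_new, h_new
            if np.max(np.abs(grad)) < _SCORE_TOL and abs(delta_ll) < _LOGLIK_TOL:
                converged = True
                break
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-hess)
            warnings.append("singular information matrix; pseudo-inverse covariance")
        if np.max(np.abs(beta)) > _DIVERGENCE_BOUND:
            warnings.append(
                "possible monotone likelihood (complete separation): "
                f"|coef| > {_DIVERGENCE_BOUND}")
            converged = False
        if not converged and not warnings:
            warnings.append("Newton-Raphson did not converge")

    se = np.sqrt(np.clip(np.diag(cov), 0.0, None)) if p else np.empty(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    wald_p = 2.0 * stats.norm.sf(np.abs(z)) if p else np.empty(0)

    # Breslow baseline cumulative hazard on the original covariate scale
    w_orig = np.exp(np.clip(X @ beta, -500, 500)) if p else np.ones(n)
    order = np.argsort(t, kind="stable")
    ts_, es_, ws_ = t[order], e[order], w_orig[order]
    ut_ = np.unique(ts_[es_])
    fi = np.searchsorted(ts_, ut_, side="left")
    S0suf = np.concatenate((np.cumsum(ws_[::-1])[::-1], [0.0]))
    d_ = np.zeros(len(ut_))
    np.add.at(d_, np.searchsorted(ut_, ts_[es_]), 1.0)
    cumhaz = np.cumsum(d_ / S0suf[fi])

    with np.errstate(over="ignore"):  # diverged terms report an infinite bound
        hr = np.exp(beta)
        ci_lo = np.exp(beta - _Z975 * se)
        ci_hi = np.exp(beta + _Z975 * se)
    return CoxFit(
        covariate_names=names,
        coefficients=beta,
        covariance=cov,
        hazard_ratios=hr,
        hr_ci_lower=ci_lo,
        hr_ci_upper=ci_hi,
        wald_p=wald_p,
        se=se,
        loglik=ll,
        loglik_null=ll0,
        baseline_times=ut_,
        baseline_cumhaz=cumhaz,
        converged=converged,
        n=n,
        n_events=n_events,
        ties=ties,
        warnings=warnings,
    )


def fit_cox(cohort, covariates, outcome="os", ties="efron") -> CoxFit:
    """Fit a Cox proportional-hazards model on a cohort.

    ``covariates`` is a list of design covariate names or a named set
    ('clinical_only' / 'clinical_plus_path'); ``outcome`` selects overall
    survival or time to progression.
    """
    Xdf = cohort.design_matrix(covariates)
    t, e = cohort.outcome(outcome)
    return fit_cox_arrays(t, e, Xdf, ties=ties)


# ---------------------------------------------------------------------------
# Backward elimination
# ---------------------------------------------------------------------------

def backward_eliminate(cohort, covariates, alpha=0.05, outcome="os", forced=(),
                       criterion="wald", ties="efron") -> CoxFit:
    """Stepwise backward elimination at significance level ``alpha``.

    Repeatedly removes the least significant non-forced covariate (largest
    p >= alpha, ties broken toward the covariate later in the declared order)
    and refits, until every remaining covariate is significant. ``criterion``
    is 'wald' (default) or 'lr' (likelihood-ratio drop test). The returned
    fit carries the removal history in ``elimination_trace``; an empty final
    model (when nothing is forced) is allowed and recorded.
    """
    if isinstance(covariates, str):
        Xall = cohort.design_matrix(covariates)
        covariates = list(Xall.columns)
    else:
        covariates = list(covariates)
        Xall = cohort.design_matrix(covariates)
    t, e = cohort.outcome(outcome)
    return backward_eliminate_arrays(t, e, Xall, alpha=alpha, forced=forced,
                                     criterion=criterion, ties=ties)


def backward_eliminate_arrays(times, events, Xdf: pd.DataFrame, alpha=0.05,
                              forced=(), criterion="wald", ties="efron") -> CoxFit:
    """Array-level backward elimination; see :func:`backward_eliminate`."""
    covariates = list(Xdf.columns)
    Xall = Xdf
    forced = list(forced)
    for f in forced:
        if f not in covariates:
            raise ValueError(f"forced covariate '{f}' not among candidates")
    if criterion not in ("wald", "lr"):
        raise ValueError("criterion must be 'wald' or 'lr'")
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    if alpha >= 1.0:  # boundary: every variable is retained
        fit = fit_cox_arrays(t, e, Xall, names=covariates, ties=ties)
        fit.elimination_trace = []
        return fit

    current = list(covariates)
    trace: list[dict] = []
    step = 0
    while True:
        fit = fit_cox_arrays(t, e, Xall[current], names=current, ties=ties)
        removable = [c for c in current if c not in forced]
        if not removable:
            break
        if criterion == "wald":
            pvals = {c: fit.wald_p[current.index(c)] for c in removable}
        else:
            pvals = {}
            for c in removable:
                rest = [x for x in current if x != c]
                ll_red = (fit_cox_arrays(t, e, Xall[rest], names=rest, ties=ties).loglik
                          if rest else _null_ll(t, e, ties))
                lr = max(0.0, 2.0 * (fit.loglik - ll_red))
                pvals[c] = float(stats.chi2.sf(lr, 1))
        # worst covariate; ties resolved toward the later declared position
        worst = max(removable, key=lambda c: (pvals[c], covariates.index(c)))
        if pvals[worst] < alpha:
            break
        step += 1
        trace.append({"step": step, "removed": worst, "p": float(pvals[worst])})
        current.remove(worst)
        if not current:
            fit = fit_cox_arrays(t, e, np.empty((len(t), 0)), names=[], ties=ties)
            break
    fit.elimination_trace = trace
    return fit


def _null_ll(t, e, ties):
    return fit_cox_arrays(t, e, np.empty((len(t), 0)), names=[], ties=ties).loglik


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PHDiagnostics:
    covariate_names: list
    schoenfeld_corr: np.ndarray       # residual vs failure-time-rank correlation
    schoenfeld_p: np.ndarray
    time_interaction_p: np.ndarray    # Wald p for covariate x g(t) term

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "schoenfeld_corr": self.schoenfeld_corr,
            "schoenfeld_p": self.schoenfeld_p,
            "time_interaction_p": self.time_interaction_p,
        }, index=self.covariate_names)


def schoenfeld_residuals(fit: CoxFit, times, events, X):
    """Schoenfeld residuals (one row per event): x_i minus the risk-set mean."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    X = np.asarray(X, float)
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    w = np.exp(np.clip(X @ fit.coefficients, -500, 500))
    S0suf = np.concatenate((np.cumsum(w[::-1])[::-1], [0.0]))
    S1suf = np.concatenate((np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1],
                            np.zeros((1, X.shape[1]))))
    ev = np.flatnonzero(e)
    idx = np.searchsorted(t, t[ev], side="left")
    xbar = S1suf[idx] / S0suf[idx][:, None]
    return t[ev], X[ev] - xbar


def ph_diagnostics(fit: CoxFit, cohort, outcome="os", g=None) -> PHDiagnostics:
    """Proportional-hazards checks for every covariate of a fitted model.

    Correlates each covariate's Schoenfeld residuals with the rank order of
    the failure times (t-test p), and Wald-tests an added covariate-by-g(t)
    interaction (g = identity by default), one covariate at a time.
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    t, e = cohort.outcome(outcome)
    X = cohort.design_matrix(fit.covariate_names).to_numpy(float)
    if int(np.sum(e)) < 3:
        raise ValueError("proportional-hazards diagnostics require at least 3 events")
    if g is None:
        g = lambda s: s

    ev_t, resid = schoenfeld_residuals(fit, t, e, X)
    ranks = stats.rankdata(ev_t)
    p_cov = len(fit.covariate_names)
    corr = np.empty(p_cov)
    corr_p = np.empty(p_cov)
    for j in range(p_cov):
        r = resid[:, j]
        if np.std(r) == 0 or np.std(ranks) == 0:
            corr[j], corr_p[j] = 0.0, 1.0
        else:
            corr[j], corr_p[j] = stats.pearsonr(r, ranks)

    ti_p = np.array([
        _time_interaction_wald_p(t, e, X, fit.coefficients, j, g) for j in range(p_cov)
    ])
    return PHDiagnostics(list(fit.covariate_names), corr, corr_p, ti_p)


def _time_interaction_wald_p(times, events, X, beta_init, j, g):
    """Wald p for gamma in a model adding z_i(t) = x_ij * g(t).

    The interaction covariate varies over event times, so the partial
    likelihood is accumulated risk set by risk set (quadratic cost; intended
    for the reduced models diagnostics run on).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    n, p = X.shape
    ut = np.unique(t[e])
    gt = np.asarray([g(u) for u in ut], dtype=float)
    gt = gt - gt.mean()  # center g(t) to decorrelate from the main effect
    first_idx = np.searchsorted(t, ut, side="left")
    ev_by_time = [np.flatnonzero(e & (t == u)) for u in ut]
    xj = X[:, j]

    def derivs(theta):
        b, gam = theta[:p], theta[p]
        eta0 = np.clip(X @ b, -500, 500)
        ll, grad, hess = 0.0, np.zeros(p + 1), np.zeros((p + 1, p + 1))
        for k, u in enumerate(ut):
            i0 = first_idx[k]
            idx = slice(i0, n)
            zr = xj[idx] * gt[k]
            w = np.exp(np.clip(eta0[idx] + gam * zr, -500, 500))
            Z = np.concatenate((X[idx], zr[:, None]), axis=1)
            S0 = w.sum()
            S1 = w @ Z
            S2 = (w[:, None] * Z).T @ Z
            rows = ev_by_time[k]
            d = len(rows)
            zev = np.concatenate((X[rows], (xj[rows] * gt[k])[:, None]), axis=1)
            ll += float(eta0[rows].sum() + gam * (xj[rows] * gt[k]).sum()) - d * np.log(S0)
            grad += zev.sum(axis=0) - d * S1 / S0
            hess -= d * (S2 / S0 - np.outer(S1 / S0, S1 / S0))
        return ll, grad, hess

    theta = np.concatenate((beta_init, [0.0]))
    ll, grad, hess = derivs(theta)
    for _ in range(_MAX_ITER):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        scale = 1.0
        for _h in range(_MAX_HALVINGS):
            cand = theta + scale * step
            ll_new, g_new, h_new = derivs(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        delta = ll_new - ll
        theta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.max(np.abs(grad)) < 1e-5 and abs(delta) < 1e-8:
            break
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    se = np.sqrt(max(cov[p, p], 0.0))
    if se == 0:
        return 1.0
    z = theta[p] / se
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Absolute survival from the baseline cumulative hazard
# ---------------------------------------------------------------------------

def baseline_survival(fit: CoxFit, covariate_vector):
    """Return the step function t -> S(t; x) = exp(-Lambda0(t) * exp(beta' x))."""
    x = np.asarray(covariate_vector, dtype=float).ravel()
    if len(x) != len(fit.coefficients):
        raise ValueError("covariate vector length does not match the fit")
    risk = float(np.exp(np.clip(x @ fit.coefficients, -500, 500))) if len(x) else 1.0

    def S(t):
        tt = np.asarray(t, dtype=float)
        if np.any(tt < 0):
            raise ValueError("survival evaluated at negative time")
        idx = np.searchsorted(fit.baseline_times, tt, side="right") - 1
        ch = np.where(idx < 0, 0.0, np.concatenate(([0.0], fit.baseline_cumhaz))[idx + 1])
        out = np.exp(-ch * risk)
        return float(out) if out.ndim == 0 else out

    return S
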