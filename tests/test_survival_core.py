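"""Survival machinery against brute-force oracles and an independent library."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from neoprog.cohort import Cohort
from neoprog.survival import (backward_eliminate, baseline_survival, fit_cox_arrays,
                              km_estimate, logrank_test, ph_diagnostics,
                              stratified_logrank_test)
from neoprog.synthetic import GeneratorConfig, generate_cohort

lifelines = pytest.importorskip("lifelines")


# ---------------------------------------------------------------------------
# Independent oracles (deliberately plain-Python, loop-based)
# ---------------------------------------------------------------------------

def brute_logrank_two_groups(times, events, groups):
    """Sum of observed-minus-expected with hypergeometric variance terms."""
    o1 = e1 = v = 0.0
    for u in sorted({t for t, e in zip(times, events) if e}):
        at_risk = [i for i, t in enumerate(times) if t >= u]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if groups[i] == 1)
        dead = [i for i, (t, e) in enumerate(zip(times, events)) if e and t == u]
        d = len(dead)
        d1 = sum(1 for i in dead if groups[i] == 1)
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n - d) / (n - 1) * n1 * (n - n1) / n ** 2
    return (o1 - e1) ** 2 / v


def brute_partial_loglik(b, times, events, x, method):
    """Cox partial log-likelihood for one covariate, Efron or Breslow ties."""
    ll = 0.0
    for u in sorted({t for t, e in zip(times, events) if e}):
        dead = [i for i, (t, e) in enumerate(zip(times, events)) if e and t == u]
        risk = [i for i, t in enumerate(times) if t >= u]
        s0 = sum(math.exp(b * x[j]) for j in risk)
        s0d = sum(math.exp(b * x[j]) for j in dead)
        d = len(dead)
        ll += sum(b * x[i] for i in dead)
        for l in range(d):
            c = l / d if method == "efron" else 0.0
            ll -= math.log(s0 - c * s0d)
    return ll


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_uncensored_equals_empirical_survival():
    times = [1.0, 2.0, 3.0]
    km = km_estimate(times, [True, True, True])
    np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 200)
    km = km_estimate(t, np.ones(200, bool))
    grid = np.quantile(t, [0.1, 0.4, 0.8])
    np.testing.assert_allclose(km.at(grid), [(t > g).mean() for g in grid], atol=1e-12)


def test_km_all_censored_is_flat_one():
    km = km_estimate([5.0, 8.0, 2.0], [False, False, False])
    assert km.all_censored
    assert km.at(100.0) == 1.0


def test_km_negative_time_rejected():
    with pytest.raises(ValueError):
        km_estimate([-1.0, 2.0], [True, True])


def test_km_matches_lifelines_with_censoring():
    rng = np.random.default_rng(1)
    t = rng.exponential(12, 500)
    c = rng.uniform(0, 30, 500)
    obs, e = np.minimum(t, c), t <= c
    km = km_estimate(obs, e)
    kmf = lifelines.KaplanMeierFitter().fit(obs, e)
    grid = np.linspace(0.5, 25, 9)
    np.testing.assert_allclose(km.at(grid), kmf.predict(grid).to_numpy(), atol=1e-10)


def test_greenwood_se_close_to_bootstrap():
    cohort = generate_cohort(GeneratorConfig(n=500, seed=21))
    t, e = cohort.outcome("os")
    km = km_estimate(t, e)
    rng = np.random.default_rng(2)
    horizons = np.array([24.0, 48.0, 72.0])
    boots = np.empty((400, len(horizons)))
    for b in range(400):
        idx = rng.integers(0, len(t), len(t))
        boots[b] = km_estimate(t[idx], e[idx]).at(horizons)
    boot_se = boots.std(axis=0, ddof=1)
    ratio = km.se_at(horizons) / boot_se
    assert np.all((ratio > 0.85) & (ratio < 1.15))


@given(st.integers(0, 2**31 - 1))
def test_km_weighted_unit_weights_identity(seed):
    rng = np.random.default_rng(seed)
    n = 40
    t = rng.exponential(10, n)
    e = rng.random(n) < 0.7
    if not e.any():
        e[0] = True
    a = km_estimate(t, e)
    b = km_estimate(t, e, weights=np.ones(n))
    np.testing.assert_array_equal(a.survival, b.survival)
    np.testing.assert_array_equal(a.greenwood_se, b.greenwood_se)
    assert np.all(np.diff(a.survival) <= 1e-12)  # monotone non-increasing


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_is_zero():
    t = [3.0, 5.0, 7.0, 9.0]
    e = [True, True, False, True]
    res = logrank_test(t + t, e + e, [0] * 4 + [1] * 4)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)


def test_logrank_matches_hand_enumeration_oracle():
    times = [1, 2, 3, 4, 5, 6]
    events = [1, 1, 1, 0, 1, 1]
    groups = [0, 0, 0, 1, 1, 1]
    res = logrank_test(times, events, groups)
    assert res.chi_square == pytest.approx(5.051660516605167, rel=1e-12)
    assert res.chi_square == pytest.approx(
        brute_logrank_two_groups(times, events, groups), rel=1e-12)
    assert res.df == 1


def test_logrank_errors():
    with pytest.raises(ValueError):
        logrank_test([1, 2], [True, True], [0, 0])


def test_logrank_label_permutation_invariance():
    rng = np.random.default_rng(3)
    t = rng.exponential(5, 60)
    e = rng.random(60) < 0.8
    g = rng.integers(0, 3, 60)
    a = logrank_test(t, e, g).chi_square
    relabel = np.array([2, 0, 1])[g]
    assert logrank_test(t, e, relabel).chi_square == pytest.approx(a, rel=1e-12)


def test_logrank_power_under_strong_effect():
    rng = np.random.default_rng(4)
    n = 500
    t0 = rng.exponential(10, n)
    t1 = rng.exponential(50, n)  # hazard ratio 0.2
    res = logrank_test(np.r_[t0, t1], np.ones(2 * n, bool), np.r_[np.zeros(n), np.ones(n)])
    assert res.p_value < 1e-6


def test_logrank_equals_cox_score_test():
    """Analytic identity: two-sample log-rank = score test of the null Cox
    fit on the group indicator (Breslow ties)."""
    from neoprog.survival import _pl_derivatives, _risk_structure
    rng = np.random.default_rng(5)
    t = np.round(rng.exponential(8, 80), 1)
    e = rng.random(80) < 0.8
    g = (rng.random(80) < 0.5).astype(float)
    chi = logrank_test(t, e, g).chi_square
    struct = _risk_structure(t, e, g[:, None], "breslow")
    _, grad, hess = _pl_derivatives(np.zeros(1), *struct, "breslow")
    score_stat = float(grad[0] ** 2 / -hess[0, 0])
    # identity is exact up to the variance convention (n-1 vs n per tie set)
    assert chi == pytest.approx(score_stat, rel=0.02)


def test_stratified_logrank_reduces_to_plain_with_one_stratum():
    rng = np.random.default_rng(6)
    t = rng.exponential(5, 50)
    e = rng.random(50) < 0.7
    g = rng.integers(0, 2, 50)
    plain = logrank_test(t, e, g)
    strat = stratified_logrank_test(t, e, g, np.zeros(50))
    assert strat.chi_square == pytest.approx(plain.chi_square, rel=1e-12)


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

def test_cox_matches_grid_search_oracle_no_ties():
    times = [1, 2, 3, 4, 5, 6]
    events = [1, 1, 0, 1, 1, 1]
    x = np.array([1, 0, 1, 0, 1, 0], float)
    fit = fit_cox_arrays(times, events, x[:, None], names=["x"])
    assert fit.coefficients[0] == pytest.approx(0.2739, abs=1e-4)  # frozen grid optimum
    # local-optimum check against the brute-force likelihood
    b = fit.coefficients[0]
    ll = brute_partial_loglik(b, times, events, x, "efron")
    for db in (-0.01, 0.01):
        assert ll >= brute_partial_loglik(b + db, times, events, x, "efron")


@pytest.mark.parametrize("ties, frozen", [("efron", 0.2352), ("breslow", 0.1815)])
def test_cox_tie_methods_match_grid_search(ties, frozen):
    x = np.array([1, 1, 0, 0, 1, 0, 1, 0], float)
    t = [2, 2, 2, 3, 3, 5, 6, 7]
    e = [1, 1, 1, 1, 0, 1, 1, 1]
    fit = fit_cox_arrays(t, e, x[:, None], names=["x"], ties=ties)
    assert fit.coefficients[0] == pytest.approx(frozen, abs=1e-4)
    b = fit.coefficients[0]
    ll = brute_partial_loglik(b, t, e, x, ties)
    for db in (-0.01, 0.01):
        assert ll >= brute_partial_loglik(b + db, t, e, x, ties)


def test_cox_matches_lifelines_multivariable():
    rng = np.random.default_rng(7)
    n = 300
    X = rng.standard_normal((n, 3))
    beta = np.array([0.6, -0.4, 0.0])
    t = rng.exponential(1 / (0.05 * np.exp(X @ beta)))
    c = rng.uniform(2, 40, n)
    obs, e = np.minimum(t, c), t <= c
    fit = fit_cox_arrays(obs, e, X, names=list("abc"))
    df = pd.DataFrame(X, columns=list("abc"))
    df["T"], df["E"] = obs, e
    cph = lifelines.CoxPHFitter().fit(df, "T", "E")
    np.testing.assert_allclose(fit.coefficients, cph.params_.to_numpy(), atol=1e-4)
    np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-4)
    assert fit.converged


def test_cox_errors_and_separation_flag():
    t = np.arange(1.0, 9.0)
    e = np.ones(8, bool)
    with pytest.raises(ValueError, match="zeros"):
        fit_cox_arrays(t, e, np.zeros((8, 1)), names=["zeros"])
    with pytest.raises(ValueError):
        fit_cox_arrays(t, np.zeros(8, bool), np.arange(8.0)[:, None])
    # perfectly separating covariate: monotone likelihood must be flagged
    x = (t > 4).astype(float)  # all early deaths have x=0
    fit = fit_cox_arrays(t, e, x[:, None], names=["sep"])
    assert not fit.converged
    assert any("monotone" in w for w in fit.warnings)


def test_baseline_survival_identity_and_monotonicity():
    rng = np.random.default_rng(8)
    n = 200
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1 / (0.08 * np.exp(0.7 * x)))
    fit = fit_cox_arrays(t, np.ones(n, bool), x[:, None], names=["x"])
    S0 = baseline_survival(fit, [0.0])
    np.testing.assert_allclose(S0(fit.baseline_times),
                               np.exp(-fit.baseline_cumhaz), atol=1e-12)
    grid = np.linspace(0, 40, 50)
    S1 = baseline_survival(fit, [1.0])
    vals = S1(grid)
    assert np.all(np.diff(vals) <= 1e-12)
    with pytest.raises(ValueError):
        S1(-1.0)


def test_baseline_survival_matches_closed_form_at_scale():
    rng = np.random.default_rng(9)
    n = 10000
    rate, beta = 0.03, 0.8
    x = (rng.random(n) < 0.4).astype(float)
    t = rng.exponential(1 / (rate * np.exp(beta * x)))
    fit = fit_cox_arrays(t, np.ones(n, bool), x[:, None], names=["x"])
    S = baseline_survival(fit, [1.0])
    for h in (5.0, 15.0, 30.0):
        closed = math.exp(-rate * math.exp(beta) * h)
        assert S(h) == pytest.approx(closed, abs=0.02)


# ---------------------------------------------------------------------------
# Backward elimination
# ---------------------------------------------------------------------------

def _cohort_with_noise(n, seed, k_noise=5):
    cohort = generate_cohort(GeneratorConfig(n=n, seed=seed))
    rng = np.random.default_rng(seed + 10_000)
    spec = dict(cohort.design_spec)
    for j in range(k_noise):
        noise = (rng.random(n) < 0.5).astype(float)
        spec[f"noise{j}"] = (lambda col: (lambda df: col))(noise)
    return Cohort(cohort.df, spec)


def test_backward_elimination_keeps_signal_drops_noise():
    reps, kept_true, kept_noise, n_noise_total = 20, 0, 0, 0
    for r in range(reps):
        cohort = _cohort_with_noise(2000, seed=100 + r)
        names = ["pcr"] + [f"noise{j}" for j in range(5)]
        fit = backward_eliminate(cohort, names, alpha=0.05)
        kept_true += "pcr" in fit.covariate_names
        kept_noise += sum(1 for c in fit.covariate_names if c.startswith("noise"))
        n_noise_total += 5
    assert kept_true >= 0.95 * reps
    assert kept_noise / n_noise_total < 0.15  # ~ alpha with selection noise


def test_backward_elimination_all_noise_calibration():
    reps, empty = 30, 0
    for r in range(reps):
        cohort = _cohort_with_noise(400, seed=500 + r, k_noise=4)
        fit = backward_eliminate(cohort, [f"noise{j}" for j in range(4)], alpha=0.05)
        empty += len(fit.covariate_names) == 0
        assert fit.elimination_trace is not None
    # P(empty) ~ (1-alpha)^4 ~ 0.81; allow a wide binomial band
    assert 0.55 <= empty / reps <= 1.0


def test_backward_elimination_alpha_one_keeps_full_model(cohort157):
    fit = backward_eliminate(cohort157, ["pcr", "cn3", "female"], alpha=1.0)
    assert fit.covariate_names == ["pcr", "cn3", "female"]
    assert fit.elimination_trace == []


def test_backward_elimination_lr_criterion_agrees_on_strong_signal(cohort1000):
    wald = backward_eliminate(cohort1000, ["pcr", "cn3", "female"], criterion="wald")
    lr = backward_eliminate(cohort1000, ["pcr", "cn3", "female"], criterion="lr")
    assert "pcr" in wald.covariate_names
    assert "pcr" in lr.covariate_names


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def _ph_cohort(n, seed, time_varying=False):
    """Single-covariate cohort wrapped for diagnostics; optionally a
    piecewise effect (HR 4 before t=8, HR 0.25 after)."""
    rng = np.random.default_rng(seed)
    base = generate_cohort(GeneratorConfig(n=n, seed=seed))
    x = (rng.random(n) < 0.5).astype(float)
    lam = 0.05
    if not time_varying:
        t = rng.exponential(1 / (lam * np.exp(0.5 * x)))
    else:
        # invert the piecewise cumulative hazard
        t0, hr1, hr2 = 8.0, 4.0, 0.25
        u = rng.exponential(1.0, n)
        rate1 = lam * np.where(x == 1, hr1, 1.0)
        rate2 = lam * np.where(x == 1, hr2, 1.0)
        t = np.where(u < rate1 * t0, u / rate1, t0 + (u - rate1 * t0) / rate2)
    df = base.df.copy()
    df["os_months"] = t
    df["os_event"] = True
    df["ttp_months"] = np.minimum(df["ttp_months"], t)
    spec = dict(base.design_spec)
    spec["xdiag"] = (lambda col: (lambda d: col[: len(d)]))(x)
    return Cohort(df, spec)


def test_ph_diagnostics_type_one_error_calibrated():
    detections_corr = detections_ti = 0
    reps = 30
    for r in range(reps):
        cohort = _ph_cohort(250, seed=900 + r)
        fit = fit_cox_arrays(*cohort.outcome("os"),
                             cohort.design_matrix(["xdiag"]), names=["xdiag"])
        diag = ph_diagnostics(fit, cohort)
        detections_corr += diag.schoenfeld_p[0] < 0.05
        detections_ti += diag.time_interaction_p[0] < 0.05
    assert detections_corr / reps <= 0.17  # binomial band around 0.05
    assert detections_ti / reps <= 0.17


def test_ph_diagnostics_detects_time_varying_effect():
    detected = 0
    for r in range(8):
        cohort = _ph_cohort(1000, seed=950 + r, time_varying=True)
        fit = fit_cox_arrays(*cohort.outcome("os"),
                             cohort.design_matrix(["xdiag"]), names=["xdiag"])
        diag = ph_diagnostics(fit, cohort)
        detected += (diag.schoenfeld_p[0] < 0.05) or (diag.time_interaction_p[0] < 0.05)
    assert detected >= 7


def test_ph_diagnostics_range_and_event_floor():
    cohort = _ph_cohort(100, seed=999)
    fit = fit_cox_arrays(*cohort.outcome("os"),
                         cohort.design_matrix(["xdiag"]), names=["xdiag"])
    diag = ph_diagnostics(fit, cohort)
    assert -1.0 <= diag.schoenfeld_corr[0] <= 1.0
    few = cohort.df.iloc[:3].copy()
    few.loc[few.index[1:], "os_event"] = False
    with pytest.raises(ValueError, match="3 events"):
        ph_diagnostics(fit, Cohort(few, cohort.design_spec))
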