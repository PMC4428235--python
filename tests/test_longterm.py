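"""Fractional long-term-survivor weights and weighted marker diagnostics."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency, spearmanr

from neoprog.cohort import Cohort
from neoprog.longterm import (LongTermWeights, binary_rank_correlation, cmh_test,
                              longterm_weights, marker_diagnostics,
                              marker_diagnostics_from_cells, suv_response_classify)
from neoprog.survival import CoxFit, backward_eliminate, fit_cox_arrays
from neoprog.synthetic import GeneratorConfig, expand_table, generate_cohort, marker_table_fixture


@pytest.fixture(scope="module")
def weighted_cohort():
    cohort = generate_cohort(GeneratorConfig(n=400, seed=33))
    fit = backward_eliminate(cohort, ["pcr", "cn3", "female", "age_years"],
                             forced=["age_years"])
    return cohort, fit, longterm_weights(cohort, fit, 36.0)


def test_weight_classification_rules(weighted_cohort):
    cohort, _fit, w = weighted_cohort
    t, e = cohort.outcome("os")
    assert np.all((w.weights >= 0) & (w.weights <= 1))
    # anyone followed past the threshold is an observed long-term survivor
    assert np.all(w.weights[t >= 36] == 1.0)
    assert all(s == "observed" for s in w.source[t >= 36])
    # deaths before the threshold are observed short-term survivors
    dead_short = e & (t < 36)
    assert np.all(w.weights[dead_short] == 0.0)
    # censored before the threshold: strictly fractional conditional weights
    alive_short = ~e & (t < 36)
    assert alive_short.any()
    assert np.all((w.weights[alive_short] > 0) & (w.weights[alive_short] < 1))
    assert all(s == "conditional" for s in w.source[alive_short])


def test_threshold_must_be_positive(weighted_cohort):
    cohort, fit, _ = weighted_cohort
    with pytest.raises(ValueError):
        longterm_weights(cohort, fit, 0.0)


def test_conditional_weight_matches_exponential_closed_form():
    """Exponential event times with a binary covariate: the conditional
    weight of a patient censored at time s is exp(-lambda_x * (36 - s))."""
    rng = np.random.default_rng(44)
    n = 20000
    rate, beta = 0.03, 0.7
    base = generate_cohort(GeneratorConfig(n=n, seed=44))
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1 / (rate * np.exp(beta * x)))
    df = base.df.copy()
    df["os_months"] = t
    df["os_event"] = True
    df["ttp_months"] = np.minimum(df["ttp_months"], t)
    # censor two reference patients at 18 months
    for i, xi in ((0, 0.0), (1, 1.0)):
        x[i] = xi
        df.loc[i, "os_months"] = 18.0
        df.loc[i, "os_event"] = False
        df.loc[i, "ttp_months"] = min(df.loc[i, "ttp_months"], 18.0)
    spec = dict(base.design_spec)
    spec["xbin"] = (lambda col: (lambda d: col[: len(d)]))(x)
    cohort = Cohort(df, spec)
    fit = fit_cox_arrays(*cohort.outcome("os"), cohort.design_matrix(["xbin"]),
                         names=["xbin"])
    w = longterm_weights(cohort, fit, 36.0)
    for i, lam in ((0, rate), (1, rate * math.exp(beta))):
        assert w.weights[i] == pytest.approx(math.exp(-lam * 18.0), abs=0.02)
        assert w.source[i] == "conditional"


def test_degenerate_weight_model_rejected():
    cohort = generate_cohort(GeneratorConfig(n=50, seed=2))
    t, e = cohort.outcome("os")
    if not (~e & (t < 36)).any():  # need a censored-short patient
        raise AssertionError("fixture lost its censored patient")
    huge = CoxFit(
        covariate_names=[], coefficients=np.empty(0), covariance=np.empty((0, 0)),
        hazard_ratios=np.empty(0), hr_ci_lower=np.empty(0), hr_ci_upper=np.empty(0),
        wald_p=np.empty(0), se=np.empty(0), loglik=0.0, loglik_null=0.0,
        baseline_times=np.array([1.0]), baseline_cumhaz=np.array([1e300]),
        converged=True, n=50, n_events=int(e.sum()), ties="efron")
    with pytest.raises(ValueError, match="degenerate"):
        longterm_weights(cohort, huge, 36.0)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def test_integer_weights_reduce_to_count_formulas():
    rng = np.random.default_rng(3)
    marker = rng.random(200) < 0.4
    w = (rng.random(200) < 0.5).astype(float)
    d = marker_diagnostics(marker, w)
    a = float(w[marker].sum())
    b = float((1 - w)[marker].sum())
    c = float(w[~marker].sum())
    dd = float((1 - w)[~marker].sum())
    assert d.sensitivity == pytest.approx(a / (a + c), rel=1e-12)
    assert d.specificity == pytest.approx(dd / (b + dd), rel=1e-12)
    assert d.positive_lr == pytest.approx(
        (a / (a + c)) / (1 - dd / (b + dd)), rel=1e-12)
    # patient order is irrelevant
    perm = rng.permutation(200)
    d2 = marker_diagnostics(marker[perm], w[perm])
    assert d2.sensitivity == d.sensitivity and d2.specificity == d.specificity


def test_perfect_marker():
    w = np.array([1.0, 1.0, 0.0, 0.0])
    marker = w == 1.0
    d = marker_diagnostics(marker, w)
    assert d.sensitivity == 1.0 and d.specificity == 1.0
    assert math.isinf(d.positive_lr)
    assert math.isinf(d.positive_lr_ci[1])


def test_zero_total_weight_rejected():
    with pytest.raises(ValueError):
        marker_diagnostics([True, False], np.array([1.0, 1.0]))


def test_lr_monotonicity_on_grid():
    sens_grid = np.linspace(0.2, 0.9, 8)
    spec_grid = np.linspace(0.2, 0.9, 8)
    n_pos, n_neg = 100.0, 100.0
    for spec in spec_grid:
        lrs = [marker_diagnostics_from_cells(
            (s * n_pos, (1 - spec) * n_neg, (1 - s) * n_pos, spec * n_neg)).positive_lr
            for s in sens_grid]
        assert np.all(np.diff(lrs) > 0)
    for s in sens_grid:
        lrs = [marker_diagnostics_from_cells(
            (s * n_pos, (1 - spec) * n_neg, (1 - s) * n_pos, spec * n_neg)).positive_lr
            for spec in spec_grid]
        assert np.all(np.diff(lrs) > 0)


def test_cmh_single_stratum_equals_scaled_pearson():
    cells = (44.0, 41.0, 28.0, 44.0)
    stat, _p = cmh_test([cells])
    table = np.array([[44, 41], [28, 44]])
    pearson = chi2_contingency(table, correction=False)[0]
    N = table.sum()
    assert stat == pytest.approx((N - 1) / N * pearson, rel=1e-10)


def test_cmh_multi_stratum_accumulates():
    t1 = (20.0, 10.0, 5.0, 15.0)
    t2 = (8.0, 12.0, 9.0, 11.0)
    stat_both, _ = cmh_test([t1, t2])
    stat_1, _ = cmh_test([t1])
    assert stat_both != pytest.approx(stat_1)


def test_table2_confidence_interval_style():
    """Wald interval of the nodal-clearance sensitivity matches the printed
    0.50-0.72 band."""
    d = marker_diagnostics_from_cells(marker_table_fixture("table2_row", "MNC")["cells"])
    assert round(d.sensitivity_ci[0], 2) == 0.50
    assert round(d.sensitivity_ci[1], 2) == 0.72


# ---------------------------------------------------------------------------
# Rank correlation and SUV response
# ---------------------------------------------------------------------------

def test_binary_rank_correlation_identity_and_errors():
    x = np.array([0, 1, 0, 1, 1])
    assert binary_rank_correlation(x, x).correlation == 1.0
    with pytest.raises(ValueError, match="constant"):
        binary_rank_correlation(x, np.ones(5))
    with pytest.raises(ValueError, match="binary"):
        binary_rank_correlation(x, np.array([0, 1, 2, 1, 0]))


def test_binary_rank_correlation_agrees_with_spearman():
    marker, outcome = expand_table((38, 85, 3, 31))
    mine = binary_rank_correlation(marker, outcome)
    rho, p = spearmanr(marker, outcome)
    assert mine.correlation == pytest.approx(rho, rel=1e-10)
    assert mine.p_value == pytest.approx(p, rel=1e-6)


def test_binary_rank_correlation_equals_phi_formula():
    a, b, c, d = 8, 9, 8, 33
    marker, outcome = expand_table((a, b, c, d))
    phi = (a * d - b * c) / math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    assert binary_rank_correlation(marker, outcome).correlation == pytest.approx(
        phi, rel=1e-10)


def test_suv_classification_boundary():
    assert suv_response_classify(0.29) == "responder"
    assert suv_response_classify(0.30) == "non_responder"  # cutoff is inclusive-above
    assert suv_response_classify(float("nan")) is None
    out = suv_response_classify([0.1, 0.5, float("nan")])
    assert list(out) == ["responder", "non_responder", None]
    with pytest.raises(ValueError):
        suv_response_classify(-0.1)


def test_weights_container_roundtrip():
    w = LongTermWeights(np.array([0.5, 1.0]), np.array(["conditional", "observed"]), 36.0)
    assert len(w) == 2
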