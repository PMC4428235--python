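"""Fractional-weight long-term-survivor analysis of response markers.

A long-term survivor is a patient alive at least 36 months from the start of
induction chemotherapy. Deceased patients classify deterministically (weight
1 if they survived past the threshold, else 0) and so do living patients
already followed past the threshold (weight 1). A living patient censored
before the threshold contributes fractionally: with weight equal to the
conditional probability, under a fitted proportional-hazards model, of
surviving to the threshold given the follow-up already survived,

    w = S(threshold; x) / S(t_obs; x),

as a long-term survivor and with weight 1 - w as a short-term survivor.

Diagnostic statistics for a binary response marker then use the weighted
2x2 table: sensitivity = (long-term weight among marker-positives) / (total
long-term weight), specificity analogously on the short-term side, the
positive likelihood ratio LR+ = sensitivity / (1 - specificity), and a
Cochran-Mantel-Haenszel association test. With all-integer weights, every
statistic reduces to the familiar count-based formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import CoxFit

__all__ = [
    "LongTermWeights",
    "MarkerDiagnostics",
    "CorrelationResult",
    "longterm_weights",
    "marker_diagnostics",
    "marker_diagnostics_from_cells",
    "cmh_test",
    "binary_rank_correlation",
    "suv_response_classify",
    "diagnostics_table",
]

_Z975 = 1.959963984540054


@dataclass
class LongTermWeights:
    """Per-patient long-term-survivor weight in [0, 1] and its provenance."""

    weights: np.ndarray
    source: np.ndarray          # 'observed' or 'conditional'
    threshold_months: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.source = np.asarray(self.source, dtype=object)

    def __len__(self):
        return len(self.weights)


def longterm_weights(cohort, weight_model: CoxFit, threshold_months: float = 36.0) -> LongTermWeights:
    """Long-term-survivor weights for every patient of the cohort.

    ``weight_model`` must be a Cox fit on the same cohort's overall-survival
    outcome; its baseline cumulative hazard supplies the conditional survival
    probabilities of living patients with short follow-up.
    """
    if threshold_months <= 0:
        raise ValueError("threshold_months must be positive")
    t, event = cohort.outcome("os")
    n = len(t)
    names = weight_model.covariate_names
    if names:
        X = cohort.design_matrix(names).to_numpy(float)
        risk = np.exp(np.clip(X @ weight_model.coefficients, -500, 500))
    else:
        risk = np.ones(n)

    # cumulative baseline hazard at the threshold and at each observed time
    bt, bch = weight_model.baseline_times, weight_model.baseline_cumhaz
    step = np.concatenate(([0.0], bch))

    def cumhaz_at(times):
        idx = np.searchsorted(bt, np.asarray(times, float), side="right")
        return step[idx]

    ch_thr = cumhaz_at(threshold_months)
    ch_obs = cumhaz_at(t)

    w = np.empty(n)
    source = np.empty(n, dtype=object)
    long_observed = t >= threshold_months
    w[long_observed] = 1.0
    source[long_observed] = "observed"
    dead_short = event & ~long_observed
    w[dead_short] = 0.0
    source[dead_short] = "observed"
    alive_short = ~event & ~long_observed
    if np.any(alive_short):
        s_obs = np.exp(-ch_obs[alive_short] * risk[alive_short])
        if np.any(s_obs <= 0):
            raise ValueError(
                "degenerate weight model: S(t_obs; x) = 0 for a living patient")
        cond = np.exp(-(ch_thr - ch_obs[alive_short]) * risk[alive_short])
        w[alive_short] = np.clip(cond, 0.0, 1.0)
        source[alive_short] = "conditional"
    return LongTermWeights(w, source, float(threshold_months))


# ---------------------------------------------------------------------------
# Weighted diagnostic statistics
# ---------------------------------------------------------------------------

@dataclass
class MarkerDiagnostics:
    """Weighted 2x2 diagnostics of a binary marker for long-term survival."""

    cells: tuple  # (marker+/long, marker+/short, marker-/long, marker-/short)
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    positive_lr: float
    positive_lr_ci: tuple
    cmh_statistic: float
    cmh_p: float
    n_long_effective: float
    n_short_effective: float


def cmh_test(tables) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel test over K (possibly weighted) 2x2 tables.

    ``tables`` is an iterable of cells (a, b, c, d) per stratum, ordered
    (marker+/outcome+, marker+/outcome-, marker-/outcome+, marker-/outcome-).
    Continuity correction is not applied; with a single stratum the statistic
    equals (N-1)/N times the Pearson chi-square of the table.
    """
    num = 0.0
    den = 0.0
    for a, b, c, d in tables:
        N = a + b + c + d
        if N <= 1:
            continue
        num += a - (a + b) * (a + c) / N
        den += (a + b) * (c + d) * (a + c) * (b + d) / (N * N * (N - 1))
    if den == 0:
        raise ValueError("CMH test undefined: zero variance across strata")
    stat = num * num / den
    return float(stat), float(stats.chi2.sf(stat, 1))


def marker_diagnostics_from_cells(cells, n_strata_tables=None) -> MarkerDiagnostics:
    """Diagnostics from (possibly fractional) 2x2 cells; see module docstring."""
    a, b, c, d = (float(v) for v in cells)
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell")
    W_long = a + c
    W_short = b + d
    if W_long <= 0 or W_short <= 0:
        raise ValueError("both long-term and short-term totals must be positive")
    sens = a / W_long
    spec = d / W_short
    sens_se = np.sqrt(max(sens * (1 - sens), 0.0) / W_long)
    spec_se = np.sqrt(max(spec * (1 - spec), 0.0) / W_short)
    sens_ci = (max(0.0, sens - _Z975 * sens_se), min(1.0, sens + _Z975 * sens_se))
    spec_ci = (max(0.0, spec - _Z975 * spec_se), min(1.0, spec + _Z975 * spec_se))

    if spec >= 1.0:
        lr = np.inf
        # one-sided interval: lower bound from the log-method with half a
        # short-term unit moved into the false-positive cell
        b_adj = 0.5
        lr_low = (sens / (b_adj / W_short)) * np.exp(
            -_Z975 * np.sqrt((1 - sens) / max(a, 0.5) + 1.0))
        lr_ci = (lr_low, np.inf)
    else:
        lr = sens / (1 - spec)
        if a > 0 and b > 0:
            se_log = np.sqrt((1 - sens) / a + spec / b)
            lr_ci = (lr * np.exp(-_Z975 * se_log), lr * np.exp(_Z975 * se_log))
        else:
            lr_ci = (0.0, np.inf)
    cmh_stat, cmh_p = cmh_test(n_strata_tables if n_strata_tables is not None
                               else [(a, b, c, d)])
    return MarkerDiagnostics((a, b, c, d), sens, sens_ci, spec, spec_ci,
                             float(lr), lr_ci, cmh_stat, cmh_p, W_long, W_short)


def marker_diagnostics(marker_flags, weights) -> MarkerDiagnostics:
    """Weighted sensitivity/specificity/LR+ of a binary marker.

    ``weights`` is a :class:`LongTermWeights` (or a bare array of long-term
    weights in [0, 1]) aligned with ``marker_flags``.
    """
    w = weights.weights if isinstance(weights, LongTermWeights) else np.asarray(weights, float)
    m = np.asarray(marker_flags).astype(bool)
    if len(m) != len(w):
        raise ValueError("marker_flags and weights must have equal length")
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weights must lie in [0, 1]")
    a = float(w[m].sum())
    b = float((1.0 - w[m]).sum())
    c = float(w[~m].sum())
    d = float((1.0 - w[~m]).sum())
    return marker_diagnostics_from_cells((a, b, c, d))


# ---------------------------------------------------------------------------
# Rank correlation of binary classifications and SUV response
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    correlation: float
    p_value: float
    n: int


def binary_rank_correlation(x, y) -> CorrelationResult:
    """Spearman rank correlation of two binary vectors (= phi coefficient).

    For binary data the Spearman and Pearson correlations coincide with the
    phi coefficient (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) of the 2x2 table;
    the p-value uses the t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    for v, name in ((x, "x"), (y, "y")):
        vals = np.unique(v)
        if not np.all(np.isin(vals, (0, 1, True, False))):
            raise ValueError(f"{name} is not binary")
        if len(vals) < 2:
            raise ValueError(f"{name} is constant")
    xb = x.astype(float)
    yb = y.astype(float)
    r = float(np.corrcoef(xb, yb)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(float(np.sign(r)), 0.0, n)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r, p, n)


def suv_response_classify(delta_suv_max, cutoff: float = 0.3):
    """Classify metabolic response from the post/pre SUVmax ratio.

    Responder iff ratio < cutoff; absent values (None/NaN) return None and
    are excluded from subgroup analyses. Scalar in, scalar out.
    """
    scalar = np.isscalar(delta_suv_max) or delta_suv_max is None
    vals = np.atleast_1d(np.asarray(delta_suv_max, dtype=float))
    if np.any(vals[~np.isnan(vals)] < 0):
        raise ValueError("SUV ratio must be >= 0")
    out = np.where(np.isnan(vals), None,
                   np.where(vals < cutoff, "responder", "non_responder"))
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# Report table
# ---------------------------------------------------------------------------

_DEFAULT_MARKERS = ("pcr", "reg_ge_2b", "reg_ge_2a", "ypt0", "mnc")


def diagnostics_table(cohort, weights: LongTermWeights,
                      markers=_DEFAULT_MARKERS) -> pd.DataFrame:
    """One diagnostics row per histopathologic response marker."""
    rows = []
    for name in markers:
        flags = cohort.design_matrix([name])[name].to_numpy(bool)
        d = marker_diagnostics(flags, weights)
        rows.append({
            "marker": name,
            "n_marker_pos": int(flags.sum()),
            "long_term_weight_pos": d.cells[0],
            "sensitivity": d.sensitivity,
            "sens_ci_low": d.sensitivity_ci[0], "sens_ci_high": d.sensitivity_ci[1],
            "specificity": d.specificity,
            "spec_ci_low": d.specificity_ci[0], "spec_ci_high": d.specificity_ci[1],
            "positive_lr": d.positive_lr,
            "lr_ci_low": d.positive_lr_ci[0], "lr_ci_high": d.positive_lr_ci[1],
            "cmh_p": d.cmh_p,
        })
    return pd.DataFrame(rows)
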