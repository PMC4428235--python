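"""Synthetic cohort generator.

Emulates a single-centre cohort of resected stage III NSCLC patients after
induction chemotherapy and neoadjuvant radiochemotherapy: covariate marginals
match the published patient-characteristics table (n = 157 cohort), overall
survival follows a proportional-hazards model whose default true effects are
the published multivariable estimates (pCR HR 0.41, cN3 HR 1.52, female HR
0.57, age HR 1.02 per year), and censoring arises from uniform accrual plus a
fixed administrative data cutoff.

The histopathologic response hierarchy is sampled top-down so its logical
invariants hold by construction: regression grade first, then primary-tumour
complete response (ypT0), then pCR among ypT0 patients, then nodal clearance
(certain under pCR). Imaging response is drawn conditional on pCR with odds
matched to the published 2x2 tables, which reproduces the printed
response/pCR rank correlations without inventing a latent biology model.

The baseline hazard is Weibull with rate and shape jointly least-squares
calibrated so that the marginal survival of the default covariate mix passes
through the published points S(24) = 0.56, S(36) = 0.46, S(60) = 0.36; a
single-rate exponential is available but cannot reach all three points under
this covariate mix (its marginal hazard does not decay fast enough).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import Cohort, default_design_spec

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "calibrate_baseline",
    "marker_table_fixture",
    "expand_table",
]

_N_REF = 157  # reference cohort size behind the default marginals


def _default_marginals() -> dict:
    return {
        "female": 63 / _N_REF,
        # joint clinical T/N cells as printed: (cT1-3,N2), (cT1-3,N3), (cT4,N2), (cT4,N3)
        "ct_cn_joint": {("le3", 2): 81 / _N_REF, ("le3", 3): 35 / _N_REF,
                        (4, 2): 37 / _N_REF, (4, 3): 4 / _N_REF},
        # split of the lumped cT1-3 cell into categories 1/2/3 (not printed)
        "ct_within_le3": {1: 0.10, 2: 0.45, 3: 0.45},
        "pancoast": 9 / _N_REF,
        "histology": {"squamous": 58 / _N_REF, "adeno": 75 / _N_REF,
                      "large_cell": 16 / _N_REF, "nos": 7 / _N_REF,
                      "sarcomatoid": 1 / _N_REF},
        "grade": {"1": 3 / _N_REF, "2": 50 / _N_REF, "3": 94 / _N_REF,
                  "unknown": 10 / _N_REF},
        "hfrt": 80 / _N_REF,
        "induction_cis_pac": 146 / _N_REF,
        "concurrent_cis_vin": 129 / _N_REF,
        "pneumonectomy": 40 / _N_REF,
        "resection": {"R0": 143 / _N_REF, "R1": 9 / _N_REF, "R2": 4 / _N_REF},
        # histopathologic regression hierarchy (lt2A, 2A, 2B, ypT0)
        "regression_grade": {"lt2A": 22 / _N_REF, "2A": 63 / _N_REF,
                             "2B": 26 / _N_REF, "ypT0": 46 / _N_REF},
        "pcr_given_ypt0": 41 / 46,
        "mnc_given_not_pcr": 44 / 116,
        # imaging response conditional on pCR (matches the 38/85/3/31 table)
        "ct_prcr_given_pcr": 38 / 41,
        "ct_prcr_given_not_pcr": 85 / 116,
        # PET subsample and metabolic response (deltaSUVmax < 0.3)
        "pet_available": 58 / _N_REF,
        "suv_resp_given_pcr": 8 / 16,
        "suv_resp_given_not_pcr": 9 / 42,
        # distributions not printed: chosen once as realistic for this setting
        "age_mean": 58.5, "age_sd": 8.5, "age_min": 34.0, "age_max": 74.0,
        "charlson_mean": 0.8,          # Poisson mean comorbidity score
        "extra_nodes_mean": 0.8,       # positive nodes = 1 + Poisson(mean)
    }


def _default_log_hrs() -> dict:
    return {"pcr": math.log(0.41), "cn3": math.log(1.52),
            "female": math.log(0.57), "age_years": math.log(1.02)}


def _default_ttp_log_hrs() -> dict:
    return {"pcr": math.log(0.34)}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n: int = 157
    seed: int = 0
    covariate_marginals: dict = field(default_factory=_default_marginals)
    log_hazard_ratios: dict = field(default_factory=_default_log_hrs)
    ttp_log_hazard_ratios: dict = field(default_factory=_default_ttp_log_hrs)
    baseline_family: str = "weibull"        # 'weibull' or 'exponential'
    baseline_rate: float | None = None      # per month; None -> calibrated
    baseline_shape: float | None = None     # None -> calibrated (1 for exponential)
    ttp_baseline_rate: float = 0.035        # per month, reference patient
    ttp_baseline_shape: float = 1.0
    accrual_months: float = 144.0
    admin_followup_months: float = 15.0
    no_censoring: bool = False
    age_center: float = 59.0                # the per-year age effect is relative to this
    survival_targets: tuple = ((24.0, 0.56), (36.0, 0.46), (60.0, 0.36))

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.baseline_family not in ("weibull", "exponential"):
            raise ValueError("baseline_family must be 'weibull' or 'exponential'")
        if self.baseline_rate is not None and self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.ttp_baseline_rate <= 0:
            raise ValueError("ttp_baseline_rate must be positive")
        m = self.covariate_marginals
        scalar_keys = ["female", "pancoast", "hfrt", "induction_cis_pac",
                       "concurrent_cis_vin", "pneumonectomy", "pcr_given_ypt0",
                       "mnc_given_not_pcr", "ct_prcr_given_pcr",
                       "ct_prcr_given_not_pcr", "pet_available",
                       "suv_resp_given_pcr", "suv_resp_given_not_pcr"]
        for k in scalar_keys:
            v = m[k]
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"marginal '{k}' = {v} outside [0, 1]")
        for k in ("ct_cn_joint", "ct_within_le3", "histology", "grade",
                  "resection", "regression_grade"):
            probs = np.array(list(m[k].values()), dtype=float)
            # printed counts may omit a patient (e.g. thoracotomy without
            # resection); sampling renormalises, so allow small slack
            if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=0.02):
                raise ValueError(f"'{k}' probabilities must be non-negative and sum to ~1")


# ---------------------------------------------------------------------------
# Covariate sampling
# ---------------------------------------------------------------------------

def _choice(rng, table: dict, n: int):
    keys = list(table.keys())
    p = np.asarray(list(table.values()), dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return [keys[i] for i in idx]


def _sample_covariates(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> pd.DataFrame:
    m = cfg.covariate_marginals
    age = rng.normal(m["age_mean"], m["age_sd"], n)
    age = np.clip(age, m["age_min"], m["age_max"])
    sex = np.where(rng.random(n) < m["female"], "female", "male")

    tn = _choice(rng, m["ct_cn_joint"], n)
    cn = np.array([c for _, c in tn], dtype=int)
    ct = np.empty(n, dtype=int)
    le3_mask = np.array([t == "le3" for t, _ in tn])
    ct[~le3_mask] = 4
    if le3_mask.any():
        ct[le3_mask] = np.array(_choice(rng, m["ct_within_le3"], int(le3_mask.sum())))

    reg = np.array(_choice(rng, m["regression_grade"], n))
    ypt0 = reg == "ypT0"
    pcr = ypt0 & (rng.random(n) < m["pcr_given_ypt0"])
    mnc = np.where(pcr, True, rng.random(n) < m["mnc_given_not_pcr"])
    ct_resp = np.where(
        rng.random(n) < np.where(pcr, m["ct_prcr_given_pcr"], m["ct_prcr_given_not_pcr"]),
        "PRCR", "PDNC")
    pet = rng.random(n) < m["pet_available"]
    suv_resp = rng.random(n) < np.where(pcr, m["suv_resp_given_pcr"],
                                        m["suv_resp_given_not_pcr"])
    # continuous SUV ratio consistent with the responder classification cutoff 0.3
    dsuv = np.where(suv_resp, rng.uniform(0.02, 0.3, n), rng.uniform(0.3, 1.3, n))
    dsuv = np.where(pet, dsuv, np.nan)

    return pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "age_years": age,
        "sex": sex,
        "charlson": rng.poisson(m["charlson_mean"], n),
        "ct_category": ct,
        "cn_category": cn,
        "pancoast": rng.random(n) < m["pancoast"],
        "histology": _choice(rng, m["histology"], n),
        "grade": _choice(rng, m["grade"], n),
        "n_pos_mediastinal_nodes": 1 + rng.poisson(m["extra_nodes_mean"], n),
        "hfrt": rng.random(n) < m["hfrt"],
        "induction_cis_pac": rng.random(n) < m["induction_cis_pac"],
        "concurrent_cis_vin": rng.random(n) < m["concurrent_cis_vin"],
        "pneumonectomy": rng.random(n) < m["pneumonectomy"],
        "resection": _choice(rng, m["resection"], n),
        "regression_grade": reg,
        "ypt0": ypt0,
        "ypn0": mnc,
        "pcr": pcr,
        "ct_response": ct_resp,
        "delta_suv_max": dsuv,
    })


def _linear_predictor(df: pd.DataFrame, log_hrs: dict, cfg: GeneratorConfig) -> np.ndarray:
    spec = default_design_spec()
    lp = np.zeros(len(df))
    for name, beta in log_hrs.items():
        if beta == 0.0:
            continue
        if name not in spec:
            raise ValueError(f"log-hazard-ratio key '{name}' is not a design covariate")
        col = spec[name](df)
        if name == "age_years":
            col = col - cfg.age_center
        lp += beta * col
    return lp


# ---------------------------------------------------------------------------
# Baseline calibration
# ---------------------------------------------------------------------------

_CALIB_SEED = 20150506
_CALIB_N = 100_000
_calib_cache: dict = {}


def _calib_signature(cfg: GeneratorConfig):
    def freeze(x):
        if isinstance(x, dict):
            return tuple(sorted(((repr(k), freeze(v)) for k, v in x.items())))
        return x
    return (cfg.baseline_family, freeze(cfg.covariate_marginals),
            freeze(cfg.log_hazard_ratios), cfg.age_center, cfg.survival_targets)


def calibrate_baseline(cfg: GeneratorConfig) -> tuple[float, float]:
    """Least-squares fit of the baseline (rate, shape) to the survival targets.

    Minimises the squared error between the marginal survival of the
    configured covariate mix and the target points, over the rate (and, for
    the Weibull family, the shape). Deterministic: the covariate expectation
    uses an internal fixed-seed Monte-Carlo sample, independent of the cohort
    seed. Results are cached per configuration.
    """
    sig = _calib_signature(cfg)
    if sig in _calib_cache:
        return _calib_cache[sig]
    rng = np.random.default_rng(_CALIB_SEED)
    df = _sample_covariates(rng, _CALIB_N, cfg)
    R = np.exp(_linear_predictor(df, cfg.log_hazard_ratios, cfg))
    targets = cfg.survival_targets

    def marginal_survival(lam, k, t):
        return float(np.mean(np.exp(-((lam * t) ** k) * R)))

    if cfg.baseline_family == "exponential":
        def loss(logl):
            lam = math.exp(logl[0])
            return sum((marginal_survival(lam, 1.0, t) - s) ** 2 for t, s in targets)
        res = minimize(loss, [math.log(0.02)], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-14})
        out = (math.exp(res.x[0]), 1.0)
    else:
        def loss(p):
            lam, k = math.exp(p[0]), math.exp(p[1])
            return sum((marginal_survival(lam, k, t) - s) ** 2 for t, s in targets)
        res = minimize(loss, [math.log(0.03), 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-14})
        out = (math.exp(res.x[0]), math.exp(res.x[1]))
    _calib_cache[sig] = out
    return out


def _resolve_baseline(cfg: GeneratorConfig) -> tuple[float, float]:
    if cfg.baseline_rate is not None:
        shape = cfg.baseline_shape
        if shape is None:
            shape = 1.0
        return cfg.baseline_rate, shape
    rate, shape = calibrate_baseline(cfg)
    if cfg.baseline_shape is not None:
        shape = cfg.baseline_shape
    return rate, shape


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _ph_times(rng, n, rate, shape, risk):
    """Event times under cumulative hazard (rate*t)^shape * risk."""
    u = rng.uniform(size=n)
    return (1.0 / rate) * (-np.log(u) / risk) ** (1.0 / shape)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort; deterministic given ``config.seed``.

    Overall-survival and progression latent times are conditionally
    independent given covariates, each proportional-hazards with its own
    baseline and true log-hazard-ratios. Observed time to progression is
    censored by death and by the administrative cutoff, so progression times
    never exceed overall-survival times and a cause-specific Cox fit on the
    progression outcome recovers the generating effects.
    """
    config.validate()
    n = config.n
    if n == 0:
        return Cohort.from_records([])
    rng = np.random.default_rng(config.seed)
    df = _sample_covariates(rng, n, config)

    rate, shape = _resolve_baseline(config)
    risk_os = np.exp(_linear_predictor(df, config.log_hazard_ratios, config))
    t_death = _ph_times(rng, n, rate, shape, risk_os)
    risk_ttp = np.exp(_linear_predictor(df, config.ttp_log_hazard_ratios, config))
    t_prog = _ph_times(rng, n, config.ttp_baseline_rate, config.ttp_baseline_shape, risk_ttp)

    if config.no_censoring:
        censor = np.full(n, np.inf)
    else:
        entry = rng.uniform(0.0, config.accrual_months, n)
        censor = (config.accrual_months - entry) + config.admin_followup_months

    os_months = np.minimum(t_death, censor)
    os_event = t_death <= censor
    ttp_months = np.minimum(t_prog, os_months)
    ttp_event = t_prog <= os_months

    df["os_months"] = os_months
    df["os_event"] = os_event
    df["ttp_months"] = ttp_months
    df["ttp_event"] = ttp_event
    return Cohort(df)


# ---------------------------------------------------------------------------
# Printed contingency tables (worked-example fixtures)
# ---------------------------------------------------------------------------

# cells are (marker+/outcome+, marker+/outcome-, marker-/outcome+, marker-/outcome-)
_RESPONSE_TABLES = {
    # CT response (PR/CR) vs pCR, full cohort
    "ct_pcr": {"cells": (38, 85, 3, 31), "marker": "ct_response_prcr", "outcome": "pcr"},
    # metabolic response (deltaSUVmax < 0.3) vs pCR, PET subgroup
    "suv_pcr": {"cells": (8, 9, 8, 33), "marker": "suv_responder", "outcome": "pcr"},
    # CT response vs pCR restricted to the PET subgroup
    "pet_ct_pcr": {"cells": (16, 32, 1, 9), "marker": "ct_response_prcr", "outcome": "pcr"},
}

# long-term-survivor table rows: (n marker-positive, long-term among marker-positive)
# under 157 patients of whom 72 are long-term survivors
_TABLE2_ROWS = {
    "pCR": (41, 28),
    "reg_ge_2b": (72, 40),
    "reg_ge_2a": (135, 66),
    "pCR-T": (46, 29),
    "MNC": (85, 44),
}
_TABLE2_N = 157
_TABLE2_LONG = 72


def marker_table_fixture(name: str, marker: str | None = None) -> dict:
    """Printed 2x2 tables as integer-weight worked examples.

    ``name`` is one of 'ct_pcr', 'suv_pcr', 'pet_ct_pcr', or 'table2_row'
    (which requires ``marker`` in {'pCR', 'reg_ge_2b', 'reg_ge_2a', 'pCR-T',
    'MNC'}). Cells are ordered (marker+/outcome+, marker+/outcome-,
    marker-/outcome+, marker-/outcome-).
    """
    if name in _RESPONSE_TABLES:
        return dict(_RESPONSE_TABLES[name])
    if name == "table2_row":
        if marker not in _TABLE2_ROWS:
            raise KeyError(f"unknown long-term-survivor table row {marker!r}; "
                           f"options: {sorted(_TABLE2_ROWS)}")
        npos, long_pos = _TABLE2_ROWS[marker]
        a = long_pos
        b = npos - long_pos
        c = _TABLE2_LONG - long_pos
        d = (_TABLE2_N - npos) - c
        return {"cells": (a, b, c, d), "marker": marker, "outcome": "long_term_survivor",
                "n_total": _TABLE2_N, "n_long_term": _TABLE2_LONG}
    raise KeyError(f"unknown fixture {name!r}; options: "
                   f"{sorted(_RESPONSE_TABLES) + ['table2_row']}")


def expand_table(cells) -> tuple[np.ndarray, np.ndarray]:
    """Expand 2x2 integer cells into paired binary vectors (marker, outcome)."""
    a, b, c, d = (int(v) for v in cells)
    marker = np.concatenate((np.ones(a + b), np.zeros(c + d))).astype(int)
    outcome = np.concatenate((np.ones(a), np.zeros(b), np.ones(c), np.zeros(d))).astype(int)
    return marker, outcome
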