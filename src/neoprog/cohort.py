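"""Cohort data model, CSV input/output, and the covariate design used by the models.

One row per resected patient: baseline covariates, treatment variables,
histopathologic response to neoadjuvant radiochemotherapy (regression grade,
ypT0, mediastinal nodal clearance, pathologic complete remission), imaging
response, and the two outcomes (overall survival, time to progression), both
timed in months from the start of induction chemotherapy.

Encoding conventions
--------------------
All patients carry histopathologically proven mediastinal nodal disease, so the
clinical nodal category is restricted to {2, 3}; because cN2 and cN3 indicators
would sum to a constant (inestimable in a partial likelihood), only the cN3
indicator enters the design matrix. ``stage_flag`` is a neutral binary stage
indicator whose defining rule is configurable (default: cT4 or cN3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortSchemaError",
    "CohortValidationError",
    "COLUMNS",
    "CLINICAL_COVARIATES",
    "PATHOLOGIC_COVARIATES",
    "COVARIATE_SETS",
    "default_design_spec",
    "read_cohort",
    "write_cohort",
]


class CohortSchemaError(ValueError):
    """The file's header does not match the cohort schema."""


class CohortValidationError(ValueError):
    """A row violates a level set, a type, or a cross-field invariant."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if column is not None:
            prefix += f"column '{column}': "
        super().__init__(prefix + message)


SEX_LEVELS = ("male", "female")
HISTOLOGY_LEVELS = ("squamous", "adeno", "large_cell", "nos", "sarcomatoid")
GRADE_LEVELS = ("1", "2", "3", "unknown")
RESECTION_LEVELS = ("R0", "R1", "R2")
REGRESSION_LEVELS = ("lt2A", "2A", "2B", "ypT0")
CT_RESPONSE_LEVELS = ("PDNC", "PRCR")

_BOOL_COLUMNS = (
    "pancoast",
    "hfrt",
    "induction_cis_pac",
    "concurrent_cis_vin",
    "pneumonectomy",
    "ypt0",
    "ypn0",
    "pcr",
    "os_event",
    "ttp_event",
)

COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age_years",
    "sex",
    "charlson",
    "ct_category",
    "cn_category",
    "pancoast",
    "histology",
    "grade",
    "n_pos_mediastinal_nodes",
    "hfrt",
    "induction_cis_pac",
    "concurrent_cis_vin",
    "pneumonectomy",
    "resection",
    "regression_grade",
    "ypt0",
    "ypn0",
    "pcr",
    "ct_response",
    "delta_suv_max",
    "os_months",
    "os_event",
    "ttp_months",
    "ttp_event",
)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates, response markers, and outcomes."""

    patient_id: str
    age_years: float
    sex: str
    charlson: int
    ct_category: int
    cn_category: int
    pancoast: bool
    histology: str
    grade: str
    n_pos_mediastinal_nodes: int
    hfrt: bool
    induction_cis_pac: bool
    concurrent_cis_vin: bool
    pneumonectomy: bool
    resection: str
    regression_grade: str
    ypt0: bool
    ypn0: bool
    pcr: bool
    ct_response: str
    delta_suv_max: float | None
    os_months: float
    os_event: bool
    ttp_months: float
    ttp_event: bool


# ---------------------------------------------------------------------------
# Design matrix: covariate name -> encoder over the cohort frame.
# ---------------------------------------------------------------------------

def _indicator(series: pd.Series, value) -> np.ndarray:
    return (series == value).to_numpy(dtype=float)


def default_design_spec(
    stage_rule: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> dict[str, Callable[[pd.DataFrame], np.ndarray]]:
    """Ordered mapping of model covariate name -> encoding over the frame.

    ``stage_rule`` overrides the neutral stage indicator (default cT4 or cN3).
    Binary covariates encode as {0, 1}; age and count variables pass through.
    """
    if stage_rule is None:
        def stage_rule(df: pd.DataFrame) -> np.ndarray:
            return ((df["ct_category"] == 4) | (df["cn_category"] == 3)).to_numpy(float)

    spec: dict[str, Callable[[pd.DataFrame], np.ndarray]] = {
        "age_years": lambda df: df["age_years"].to_numpy(float),
        "female": lambda df: _indicator(df["sex"], "female"),
        "charlson": lambda df: df["charlson"].to_numpy(float),
        "cn3": lambda df: _indicator(df["cn_category"], 3),
        "pancoast": lambda df: df["pancoast"].to_numpy(float),
        "ct3": lambda df: _indicator(df["ct_category"], 3),
        "ct4": lambda df: _indicator(df["ct_category"], 4),
        "stage_flag": stage_rule,
        "adeno": lambda df: _indicator(df["histology"], "adeno"),
        "squamous": lambda df: _indicator(df["histology"], "squamous"),
        "grade3": lambda df: _indicator(df["grade"], "3"),
        "n_pos_mediastinal_nodes": lambda df: df["n_pos_mediastinal_nodes"].to_numpy(float),
        "hfrt": lambda df: df["hfrt"].to_numpy(float),
        "induction_cis_pac": lambda df: df["induction_cis_pac"].to_numpy(float),
        "concurrent_cis_vin": lambda df: df["concurrent_cis_vin"].to_numpy(float),
        "pneumonectomy": lambda df: df["pneumonectomy"].to_numpy(float),
        "r1": lambda df: _indicator(df["resection"], "R1"),
        "r2": lambda df: _indicator(df["resection"], "R2"),
        "ct_response_prcr": lambda df: _indicator(df["ct_response"], "PRCR"),
        "pcr": lambda df: df["pcr"].to_numpy(float),
        "mnc": lambda df: df["ypn0"].to_numpy(float),
        "reg_ge_2b": lambda df: df["regression_grade"].isin(["2B", "ypT0"]).to_numpy(float),
        "reg_ge_2a": lambda df: df["regression_grade"].isin(["2A", "2B", "ypT0"]).to_numpy(float),
        "ypt0": lambda df: df["ypt0"].to_numpy(float),
    }
    return spec


# Preoperatively available covariates (imaging response included: it is known
# before thoracotomy) versus the histopathologic response markers that require
# the resection specimen.
CLINICAL_COVARIATES: tuple[str, ...] = (
    "age_years",
    "female",
    "charlson",
    "cn3",
    "pancoast",
    "ct3",
    "ct4",
    "stage_flag",
    "adeno",
    "squamous",
    "grade3",
    "n_pos_mediastinal_nodes",
    "hfrt",
    "induction_cis_pac",
    "concurrent_cis_vin",
    "pneumonectomy",
    "r1",
    "r2",
    "ct_response_prcr",
)

PATHOLOGIC_COVARIATES: tuple[str, ...] = ("pcr", "mnc", "reg_ge_2b", "reg_ge_2a", "ypt0")

COVARIATE_SETS: dict[str, tuple[str, ...]] = {
    "clinical_only": CLINICAL_COVARIATES,
    "clinical_plus_path": CLINICAL_COVARIATES + PATHOLOGIC_COVARIATES,
}


class Cohort:
    """Validated patient cohort backed by a :class:`pandas.DataFrame`.

    Row order is preserved; ``delta_suv_max`` is the only optional field
    (absent values are ``NaN`` in the frame, ``None`` on records).
    """

    def __init__(self, df: pd.DataFrame, design_spec: Mapping[str, Callable] | None = None):
        self.df = _validate_frame(df)
        self.design_spec = dict(design_spec) if design_spec is not None else default_design_spec()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[PatientRecord], design_spec=None) -> "Cohort":
        names = [f.name for f in dc_fields(PatientRecord)]
        rows = [{n: getattr(r, n) for n in names} for r in records]
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        if len(rows) == 0:
            df = _empty_frame()
        return cls(df, design_spec)

    # -- basic protocol ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.records == other.records

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            if d["delta_suv_max"] is not None and math.isnan(d["delta_suv_max"]):
                d["delta_suv_max"] = None
            out.append(PatientRecord(**d))
        return out

    # -- design matrix -------------------------------------------------------

    def design_matrix(self, covariates: Sequence[str] | str) -> pd.DataFrame:
        """Encode the named covariates (or a named set) as a numeric frame."""
        if isinstance(covariates, str):
            try:
                covariates = COVARIATE_SETS[covariates]
            except KeyError:
                raise KeyError(
                    f"unknown covariate set '{covariates}'; options: {sorted(COVARIATE_SETS)}"
                ) from None
        data = {}
        for name in covariates:
            if name not in self.design_spec:
                raise KeyError(f"no encoding rule for covariate '{name}'")
            data[name] = self.design_spec[name](self.df)
        return pd.DataFrame(data, index=self.df.index)

    def outcome(self, which: str = "os") -> tuple[np.ndarray, np.ndarray]:
        """Return (time, event) arrays for 'os' or 'ttp'."""
        if which not in ("os", "ttp"):
            raise ValueError("outcome must be 'os' or 'ttp'")
        t = self.df[f"{which}_months"].to_numpy(float)
        e = self.df[f"{which}_event"].to_numpy(bool)
        return t, e

    def subset(self, mask) -> "Cohort":
        return Cohort(self.df.loc[np.asarray(mask)].reset_index(drop=True), self.design_spec)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})
    for c in ("age_years", "delta_suv_max", "os_months", "ttp_months"):
        df[c] = df[c].astype(float)
    for c in ("charlson", "ct_category", "cn_category", "n_pos_mediastinal_nodes"):
        df[c] = df[c].astype(int)
    for c in _BOOL_COLUMNS:
        df[c] = df[c].astype(bool)
    return df


def _check_levels(df, col, levels, errors):
    bad = ~df[col].isin(levels)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        errors.append(CohortValidationError(
            f"invalid level {df[col].iloc[i]!r}; allowed: {levels}", row=i, column=col))


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise CohortSchemaError(f"unrecognised column(s): {extra}")
    df = df[list(COLUMNS)].reset_index(drop=True)
    if len(df) == 0:
        return _empty_frame()

    errors: list[CohortValidationError] = []

    # required fields present (delta_suv_max is the only optional one)
    for col in COLUMNS:
        if col == "delta_suv_max":
            continue
        na = df[col].isna()
        if na.any():
            errors.append(CohortValidationError(
                "missing value in required column", row=int(np.flatnonzero(na)[0]), column=col))
    if errors:
        raise errors[0]

    # types; float() per element keeps the exact round-trip value that
    # pandas' default (fast, 15-digit) parser would lose
    def _exact_float(col, optional=False):
        def conv(v):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return math.nan
            try:
                return float(v)
            except (TypeError, ValueError):
                return None
        vals = df[col].map(conv)
        bad = vals.isna() & ~df[col].isna() if optional else vals.isna()
        if not optional and bad.any():
            raise CohortValidationError(
                "non-numeric value", row=int(np.flatnonzero(bad)[0]), column=col)
        df[col] = vals.astype(float)

    for col in ("age_years", "os_months", "ttp_months"):
        _exact_float(col)
    _exact_float("delta_suv_max", optional=True)
    for col in ("charlson", "ct_category", "cn_category", "n_pos_mediastinal_nodes"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise CohortValidationError(
                "non-integer value", row=int(np.flatnonzero(vals.isna())[0]), column=col)
        df[col] = vals.astype(int)
    for col in _BOOL_COLUMNS:
        df[col] = _parse_bool(df[col], col)
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("sex", "histology", "resection", "regression_grade", "ct_response"):
        df[col] = df[col].astype(str)
    df["grade"] = df["grade"].astype(str)

    # level sets
    _check_levels(df, "sex", SEX_LEVELS, errors)
    _check_levels(df, "histology", HISTOLOGY_LEVELS, errors)
    _check_levels(df, "grade", GRADE_LEVELS, errors)
    _check_levels(df, "resection", RESECTION_LEVELS, errors)
    _check_levels(df, "regression_grade", REGRESSION_LEVELS, errors)
    _check_levels(df, "ct_response", CT_RESPONSE_LEVELS, errors)
    _check_levels(df, "ct_category", (1, 2, 3, 4), errors)
    _check_levels(df, "cn_category", (2, 3), errors)
    if errors:
        raise errors[0]

    # range and cross-field invariants
    def _first_bad(mask, msg, col):
        if mask.any():
            errors.append(CohortValidationError(msg, row=int(np.flatnonzero(mask)[0]), column=col))

    _first_bad((df["age_years"] <= 0).to_numpy(), "age must be positive", "age_years")
    _first_bad((df["charlson"] < 0).to_numpy(), "must be non-negative", "charlson")
    _first_bad((df["n_pos_mediastinal_nodes"] < 0).to_numpy(),
               "must be non-negative", "n_pos_mediastinal_nodes")
    _first_bad((df["os_months"] < 0).to_numpy(), "negative survival time", "os_months")
    _first_bad((df["ttp_months"] < 0).to_numpy(), "negative progression time", "ttp_months")
    _first_bad((df["delta_suv_max"] < 0).to_numpy(), "SUV ratio must be >= 0", "delta_suv_max")
    _first_bad((df["ttp_months"] > df["os_months"]).to_numpy(),
               "time to progression exceeds overall-survival time", "ttp_months")
    _first_bad((df["pcr"] & ~(df["ypt0"] & df["ypn0"])).to_numpy(),
               "pCR requires ypT0 and mediastinal nodal clearance (ypN0)", "pcr")
    _first_bad((df["ypt0"] & (df["regression_grade"] != "ypT0")).to_numpy(),
               "ypT0 requires regression_grade 'ypT0'", "ypt0")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        errors.append(CohortValidationError(f"duplicate patient_id {dup!r}", column="patient_id"))
    if errors:
        raise errors[0]
    return df


def _parse_bool(series: pd.Series, col: str) -> pd.Series:
    if series.dtype == bool:
        return series
    mapped = series.astype(str).str.strip().str.lower().map({"true": True, "false": False})
    if mapped.isna().any():
        raise CohortValidationError(
            "expected boolean 'true'/'false'",
            row=int(np.flatnonzero(mapped.isna())[0]), column=col)
    return mapped.astype(bool)


# ---------------------------------------------------------------------------
# CSV round trip (comma-separated, UTF-8, '.' decimal, 'true'/'false' booleans)
# ---------------------------------------------------------------------------

def read_cohort(path, design_spec=None) -> Cohort:
    """Read and validate a cohort CSV.

    Raises :class:`CohortSchemaError` for header problems and
    :class:`CohortValidationError` (with row/column context) for bad values.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    return Cohort(df, design_spec)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV losslessly re-readable by :func:`read_cohort`."""
    out = cohort.df.copy()
    for col in _BOOL_COLUMNS:
        out[col] = np.where(out[col].to_numpy(bool), "true", "false")
    for col in ("age_years", "os_months", "ttp_months", "delta_suv_max"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False, encoding="utf-8")
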