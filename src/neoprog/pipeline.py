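"""End-to-end analysis pipeline with seeded reproducibility.

Stages, in the order the analysis runs: cohort (load or generate) ->
cohort summary -> overall Kaplan-Meier curve -> backward-selected Cox models
(clinico-pathologic and clinical-only, plus the time-to-progression model)
with proportional-hazards diagnostics -> fractional-weight long-term-survivor
marker diagnostics -> response-marker/pCR rank correlations -> in-sample and
cross-validated risk groupings with the difference-of-log-rank-statistics
model comparison -> recursive-partitioning survival tree -> Kaplan-Meier
curves stratified by pCR and clinical nodal category. Tables and curves are
written as CSV, fits and the tree as JSON, and a manifest records the
configuration, seeds, package versions, warnings, and a hash of every output
file, so a run is reproducible byte for byte from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .longterm import binary_rank_correlation, diagnostics_table, longterm_weights
from .riskmodel import build_risk_model, compare_models
from .rpa import grow_tree, node_summaries, tree_to_dict
from .survival import (CoxFit, backward_eliminate, km_estimate, ph_diagnostics,
                       stratified_logrank_test)
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "coxfit_to_dict", "coxfit_from_dict"]

logger = logging.getLogger("neoprog")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_csv: str | None = None              # mutually exclusive with generator
    generator: GeneratorConfig | None = None  # default: 157-patient cohort
    out_dir: str = "neoprog_out"
    alpha: float = 0.05
    threshold_months: float = 36.0
    k_folds: int = 10
    fold_seed: int = 1
    permutation_seed: int = 2
    n_permutations: int = 100
    ties: str = "efron"
    rpa_min_node: int = 20
    rpa_max_depth: int = 4

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.input_csv is not None and self.generator is not None:
            raise ValueError("give either input_csv or a generator config, not both")


# ---------------------------------------------------------------------------
# (De)serialisation helpers
# ---------------------------------------------------------------------------

def coxfit_to_dict(fit: CoxFit) -> dict:
    return {
        "covariate_names": list(fit.covariate_names),
        "coefficients": fit.coefficients.tolist(),
        "covariance": fit.covariance.tolist(),
        "hazard_ratios": fit.hazard_ratios.tolist(),
        "hr_ci_lower": fit.hr_ci_lower.tolist(),
        "hr_ci_upper": fit.hr_ci_upper.tolist(),
        "wald_p": fit.wald_p.tolist(),
        "se": fit.se.tolist(),
        "loglik": fit.loglik,
        "loglik_null": fit.loglik_null,
        "baseline_times": fit.baseline_times.tolist(),
        "baseline_cumhaz": fit.baseline_cumhaz.tolist(),
        "converged": fit.converged,
        "n": fit.n,
        "n_events": fit.n_events,
        "ties": fit.ties,
        "warnings": list(fit.warnings),
        "elimination_trace": fit.elimination_trace,
    }


def coxfit_from_dict(d: dict) -> CoxFit:
    arr = np.asarray
    return CoxFit(
        covariate_names=list(d["covariate_names"]),
        coefficients=arr(d["coefficients"], dtype=float),
        covariance=arr(d["covariance"], dtype=float).reshape(
            len(d["covariate_names"]), len(d["covariate_names"])),
        hazard_ratios=arr(d["hazard_ratios"], dtype=float),
        hr_ci_lower=arr(d["hr_ci_lower"], dtype=float),
        hr_ci_upper=arr(d["hr_ci_upper"], dtype=float),
        wald_p=arr(d["wald_p"], dtype=float),
        se=arr(d["se"], dtype=float),
        loglik=d["loglik"],
        loglik_null=d["loglik_null"],
        baseline_times=arr(d["baseline_times"], dtype=float),
        baseline_cumhaz=arr(d["baseline_cumhaz"], dtype=float),
        converged=d["converged"],
        n=d["n"],
        n_events=d["n_events"],
        ties=d["ties"],
        warnings=list(d.get("warnings", [])),
        elimination_trace=d.get("elimination_trace"),
    )


def _curve_frame(km, group: str) -> pd.DataFrame:
    return pd.DataFrame({
        "group": group,
        "time_months": km.event_times,
        "survival": km.survival,
        "greenwood_se": km.greenwood_se,
        "at_risk": km.at_risk,
        "n_events": km.n_events,
    })


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config),
                      "versions": {"neoprog": __version__,
                                   "numpy": np.__version__, "pandas": pd.__version__},
                      "stages": {}, "warnings": []}
    written: list[Path] = []

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"started_s": round(time.time() - t_start, 3)}
        return time.time()

    def done(name, t0):
        manifest["stages"][name]["elapsed_s"] = round(time.time() - t0, 3)

    # -- cohort --------------------------------------------------------------
    t0 = stage("cohort")
    if config.input_csv is not None:
        cohort = read_cohort(config.input_csv)
        manifest["cohort_source"] = str(config.input_csv)
    else:
        gen = config.generator if config.generator is not None else GeneratorConfig()
        cohort = generate_cohort(gen)
        write_cohort(cohort, out / "cohort.csv")
        written.append(out / "cohort.csv")
        manifest["cohort_source"] = "synthetic"
    if len(cohort) == 0:
        raise ValueError("stage cohort: empty cohort, nothing to analyse")
    done("cohort", t0)

    # -- cohort summary ------------------------------------------------------
    t0 = stage("summary")
    _write_csv(_cohort_summary(cohort), out / "cohort_summary.csv", written)
    done("summary", t0)

    # -- overall survival curve ----------------------------------------------
    t0 = stage("overall_km")
    t, e = cohort.outcome("os")
    km_all = km_estimate(t, e)
    _write_csv(_curve_frame(km_all, "all"), out / "km_overall.csv", written)
    manifest["overall_survival"] = {
        str(h): {"estimate": float(km_all.at(h)), "se": float(km_all.se_at(h))}
        for h in (24, 36, 60)}
    done("overall_km", t0)

    # -- prognostic models ---------------------------------------------------
    t0 = stage("models")
    fits = {}
    groupings = {}
    for label, cset in (("model1_clinical_plus_path", "clinical_plus_path"),
                        ("model2_clinical_only", "clinical_only")):
        try:
            fit, grouping = build_risk_model(cohort, cset, alpha=config.alpha,
                                             ties=config.ties)
        except ValueError as err:
            raise ValueError(f"stage models ({label}): {err}") from err
        fits[label] = fit
        groupings[label] = grouping
        manifest["warnings"].extend(f"{label}: {w}" for w in fit.warnings)
    ttp_fit = backward_eliminate(cohort, "clinical_plus_path", alpha=config.alpha,
                                 outcome="ttp", ties=config.ties)
    fits["ttp_clinical_plus_path"] = ttp_fit
    model_report = {}
    for label, fit in fits.items():
        entry = coxfit_to_dict(fit)
        if fit.covariate_names and fit.converged:
            diag = ph_diagnostics(
                fit, cohort, outcome="ttp" if label.startswith("ttp") else "os")
            entry["ph_diagnostics"] = diag.summary().to_dict(orient="index")
        model_report[label] = entry
    (out / "models.json").write_text(
        json.dumps(model_report, indent=1, default=_json_default))
    written.append(out / "models.json")
    done("models", t0)

    # -- long-term-survivor marker diagnostics --------------------------------
    t0 = stage("marker_diagnostics")
    weights = longterm_weights(cohort, fits["model1_clinical_plus_path"],
                               config.threshold_months)
    _write_csv(diagnostics_table(cohort, weights),
               out / "marker_diagnostics.csv", written)
    done("marker_diagnostics", t0)

    # -- response correlations ------------------------------------------------
    t0 = stage("correlations")
    corr = {}
    ctr = cohort.design_matrix(["ct_response_prcr", "pcr"])
    r = binary_rank_correlation(ctr["ct_response_prcr"], ctr["pcr"])
    corr["ct_response_vs_pcr"] = {"correlation": r.correlation,
                                  "p_value": r.p_value, "n": r.n}
    pet = ~cohort.df["delta_suv_max"].isna().to_numpy()
    if pet.sum() >= 10:
        sub = cohort.df.loc[pet]
        suv_resp = (sub["delta_suv_max"] < 0.3).to_numpy(int)
        pcr = sub["pcr"].to_numpy(int)
        if len(np.unique(suv_resp)) == 2 and len(np.unique(pcr)) == 2:
            r2 = binary_rank_correlation(suv_resp, pcr)
            corr["suv_response_vs_pcr_pet_subgroup"] = {
                "correlation": r2.correlation, "p_value": r2.p_value, "n": r2.n}
    (out / "correlations.json").write_text(json.dumps(corr, indent=1))
    written.append(out / "correlations.json")
    done("correlations", t0)

    # -- cross-validated model comparison -------------------------------------
    t0 = stage("cv_comparison")
    cmp = compare_models(cohort, "clinical_plus_path", "clinical_only",
                         k=config.k_folds, seed=config.fold_seed,
                         n_permutations=config.n_permutations,
                         alpha=config.alpha, ties=config.ties)
    cv_report = {
        "k": config.k_folds, "fold_seed": config.fold_seed,
        "n_permutations": config.n_permutations,
        "chi_square_clinical_plus_path": cmp.chi_square_a,
        "chi_square_clinical_only": cmp.chi_square_b,
        "delta_chi_square": cmp.delta_chi_square,
        "p_value": cmp.p_value,
        "retained_per_fold_clinical_plus_path": cmp.cv_a.retained,
        "retained_per_fold_clinical_only": cmp.cv_b.retained,
    }
    (out / "cv_comparison.json").write_text(
        json.dumps(cv_report, indent=1, default=_json_default))
    written.append(out / "cv_comparison.json")
    curves = []
    for label, cv in (("clinical_plus_path", cmp.cv_a), ("clinical_only", cmp.cv_b)):
        if not cv.degenerate:
            curves.append(_curve_frame(cv.km_high, f"{label}:high"))
            curves.append(_curve_frame(cv.km_low, f"{label}:low"))
        else:
            manifest["warnings"].append(f"cv grouping degenerate for {label}")
    for label, grouping in groupings.items():
        if not grouping.degenerate:
            curves.append(_curve_frame(grouping.km_high, f"{label}:insample_high"))
            curves.append(_curve_frame(grouping.km_low, f"{label}:insample_low"))
    _write_csv(pd.concat(curves, ignore_index=True) if curves else pd.DataFrame(),
               out / "km_risk_groups.csv", written)
    done("cv_comparison", t0)

    # -- recursive partitioning -----------------------------------------------
    t0 = stage("rpa_tree")
    tree = grow_tree(cohort, alpha=config.alpha, min_node=config.rpa_min_node,
                     max_depth=config.rpa_max_depth)
    (out / "rpa_tree.json").write_text(
        json.dumps(tree_to_dict(tree), indent=1, default=_json_default))
    written.append(out / "rpa_tree.json")
    _write_csv(node_summaries(tree), out / "rpa_nodes.csv", written)
    done("rpa_tree", t0)

    # -- pCR x nodal-category strata -------------------------------------------
    t0 = stage("strata_km")
    df = cohort.df
    pcr = df["pcr"].to_numpy(bool)
    cn3 = (df["cn_category"] == 3).to_numpy()
    strata = np.where(pcr, "pCR", "not-pCR").astype(object)
    strata = np.char.add(strata.astype(str),
                         np.where(cn3, "/cN3", "/cN2")).astype(object)
    rows = []
    frames = []
    for lev in ("pCR/cN2", "pCR/cN3", "not-pCR/cN2", "not-pCR/cN3"):
        mask = strata == lev
        if mask.sum() == 0:
            continue
        km = km_estimate(t[mask], e[mask])
        frames.append(_curve_frame(km, lev))
        rows.append({"stratum": lev, "n": int(mask.sum()),
                     "s60": float(km.at(60.0)), "s60_se": float(km.se_at(60.0))})
    _write_csv(pd.concat(frames, ignore_index=True), out / "km_pcr_cn_strata.csv", written)
    strata_report = {"s60_by_stratum": rows}
    if len(np.unique(pcr)) == 2:
        slr = stratified_logrank_test(t, e, pcr.astype(int),
                                      np.where(cn3, "cN3", "cN2"))
        strata_report["pcr_effect_stratified_logrank"] = {
            "chi_square": slr.chi_square, "p_value": slr.p_value}
    (out / "strata.json").write_text(
        json.dumps(strata_report, indent=1, default=_json_default))
    written.append(out / "strata.json")
    done("strata_km", t0)

    # -- manifest --------------------------------------------------------------
    manifest["files"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(written)}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest["files"], sort_keys=True).encode()).hexdigest()
    manifest["elapsed_s"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=_json_default))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if config.generator is not None:
        gen = asdict(config.generator)
        gen["covariate_marginals"] = {
            str(k): (v if not isinstance(v, dict) else {str(kk): vv for kk, vv in v.items()})
            for k, v in gen["covariate_marginals"].items()}
        d["generator"] = gen
    return d


def _write_csv(df: pd.DataFrame, path: Path, written: list) -> None:
    df.to_csv(path, index=False)
    written.append(path)


def _cohort_summary(cohort: Cohort) -> pd.DataFrame:
    df = cohort.df
    n = len(df)
    rows = [("total", n, 100.0)]

    def add(name, count):
        rows.append((name, int(count), round(100.0 * count / n, 1)))

    add("male", (df["sex"] == "male").sum())
    add("female", (df["sex"] == "female").sum())
    add("cN3", (df["cn_category"] == 3).sum())
    add("cT4", (df["ct_category"] == 4).sum())
    add("pancoast", df["pancoast"].sum())
    for h in ("squamous", "adeno", "large_cell", "nos", "sarcomatoid"):
        add(f"histology_{h}", (df["histology"] == h).sum())
    add("grade3", (df["grade"] == "3").sum())
    add("hfrt", df["hfrt"].sum())
    add("induction_cis_pac", df["induction_cis_pac"].sum())
    add("concurrent_cis_vin", df["concurrent_cis_vin"].sum())
    add("pneumonectomy", df["pneumonectomy"].sum())
    for r in ("R0", "R1", "R2"):
        add(f"resection_{r}", (df["resection"] == r).sum())
    add("pCR", df["pcr"].sum())
    add("MNC", df["ypn0"].sum())
    add("ypT0", df["ypt0"].sum())
    add("reg_ge_2B", df["regression_grade"].isin(["2B", "ypT0"]).sum())
    add("reg_ge_2A", df["regression_grade"].isin(["2A", "2B", "ypT0"]).sum())
    add("ct_response_PRCR", (df["ct_response"] == "PRCR").sum())
    out = pd.DataFrame(rows, columns=["characteristic", "count", "percent"])
    out.loc[len(out)] = ["age_median_years", float(df["age_years"].median()), np.nan]
    return out
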