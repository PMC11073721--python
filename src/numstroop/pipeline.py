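"""Pipeline orchestration: simulate -> clean -> fit -> analyze -> report.

Every artifact is stamped with the seed and a hash of the configuration
so that a run can be regenerated exactly; re-running with an identical
configuration produces byte-identical result JSONs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cleaning as cl
from . import stats as st
from .design import DesignConfig
from .fit import FitConfig, drift_anova, fit_all, posthoc_drift
from .io import validate_table, write_trials
from .simulate import default_truth, simulate_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger("numstroop")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        self.stage, self.code = stage, code
        super().__init__(f"[{stage}:{code}] {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one end-to-end run."""

    input_table: str | None = None      # existing trial CSV; None => simulate
    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    n_participants: int = 15
    congruent_active_boost: float = 0.5
    sim_dt: float = 1e-3
    cleaning_sd_basis: str = "per_participant"
    cleaning_sd_mult: float = 2.5
    coil_threshold_mm: float = 3.0
    fit_p_c: float = 0.05
    fit_min_trials: int = 20
    fit_restarts: int = 5
    fit_tol: float = 1e-6
    arms: tuple = ("practice", "rtms", "sce", "ddm", "distance", "covariates")

    def validate(self) -> None:
        if self.cleaning_sd_mult <= 0 or self.coil_threshold_mm <= 0:
            raise PipelineError("config", "bad_threshold", "thresholds must be positive")
        if not self.simulate and not self.input_table:
            raise PipelineError("config", "missing_input",
                                "input_table required when simulate is off")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError("config", "unknown_keys", f"unknown config keys: {sorted(unknown)}")
    if "arms" in raw:
        raw["arms"] = tuple(raw["arms"])
    return PipelineConfig(**raw)


def _dump(obj, path: Path, config: PipelineConfig) -> None:
    payload = {"config_hash": config.hash(), "seed": config.seed,
               "config": dataclasses.asdict(config), "result": obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def _log_stage(stage, rows_in, rows_out):
    logger.info("stage=%s rows_in=%d rows_out=%d", stage, rows_in, rows_out)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns {artifact name: path}."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    artifacts: dict = {}

    # --- simulate or load -------------------------------------------------
    if config.simulate:
        truth = default_truth(config.congruent_active_boost)
        dcfg = DesignConfig(n_participants=config.n_participants, seed=config.seed)
        trials, covars = simulate_study(dcfg, truth, seed=config.seed, dt=config.sim_dt)
        tpath = out / "trials.csv"
        write_trials(trials, tpath)
        covars.to_csv(out / "covariates.csv", index=False)
        artifacts["trials"] = str(tpath)
        artifacts["covariates"] = str(out / "covariates.csv")
    else:
        tpath = Path(config.input_table)
        if not tpath.exists():
            raise PipelineError("load", "missing_input", f"input table not found: {tpath}")
        rep = validate_table(tpath)
        if not rep.ok:
            raise PipelineError("load", "schema", f"{len(rep.violations)} schema violations")
        trials = pd.read_csv(tpath)
        covars = None
    _log_stage("input", len(trials), len(trials))

    # --- clean ------------------------------------------------------------
    practice = trials[trials["session"].isin(["practice1", "mri", "practice2"])]
    tms = trials[trials["session"] == "tms"]
    try:
        practice_clean, rep_p = cl.clean_practice(
            practice, sd_basis=config.cleaning_sd_basis, sd_mult=config.cleaning_sd_mult)
        tms_clean, rep_t = cl.clean_tms(
            tms, sd_basis=config.cleaning_sd_basis, sd_mult=config.cleaning_sd_mult,
            coil_threshold=config.coil_threshold_mm)
    except ValueError as e:
        raise PipelineError("clean", "cascade", str(e))
    _dump(rep_p.to_dict(), out / "cleaning_practice.json", config)
    _dump(rep_t.to_dict(), out / "cleaning_tms.json", config)
    write_trials(practice_clean, out / "cleaned_practice.csv")
    write_trials(tms_clean, out / "cleaned_tms.csv")
    artifacts.update({
        "cleaning_practice": str(out / "cleaning_practice.json"),
        "cleaning_tms": str(out / "cleaning_tms.json"),
        "cleaned_practice": str(out / "cleaned_practice.csv"),
        "cleaned_tms": str(out / "cleaned_tms.csv"),
    })
    _log_stage("clean_practice", len(practice), len(practice_clean))
    _log_stage("clean_tms", len(tms), len(tms_clean))

    report_lines = ["# Pipeline report", "", f"seed: {config.seed}",
                    f"config hash: {config.hash()}", ""]

    # --- classical analyses ----------------------------------------------
    if "practice" in config.arms:
        pr = practice_clean.copy()
        pr = pr[pr["congruency"] != "neutral"]
        pr["timepoint"] = pr["session"].where(pr["session"] != "mri",
                                              "mri" + pr["block"].astype(str))
        res = st.lmm_rt(pr, fixed=["congruency", "timepoint"],
                        posthoc_factors=["timepoint"])
        _dump(res.to_dict(), out / "practice_lmm.json", config)
        artifacts["practice_lmm"] = str(out / "practice_lmm.json")

    if "rtms" in config.arms:
        res = st.lmm_rt(tms_clean, fixed=["stimulation", "congruency", "order_group"],
                        posthoc_factors=["stimulation"])
        _dump(res.to_dict(), out / "rtms_lmm.json", config)
        artifacts["rtms_lmm"] = str(out / "rtms_lmm.json")

    if "sce" in config.arms:
        cells = (tms_clean.groupby(["participant_id", "order_group", "stimulation", "congruency"])
                 ["rt_s"].mean().mul(1000.0).rename("rt_ms").reset_index())
        piv = cells.pivot_table(index=["participant_id", "order_group", "stimulation"],
                                columns="congruency", values="rt_ms").reset_index()
        sce_results = {}
        for comp, expr in [("sce", lambda d: d["incongruent"] - d["congruent"]),
                           ("facilitation", lambda d: d["neutral"] - d["congruent"]),
                           ("interference", lambda d: d["incongruent"] - d["neutral"])]:
            tab = piv[["participant_id", "order_group", "stimulation"]].copy()
            tab[comp] = expr(piv)
            res = st.rm_anova_mixed(tab, dv=comp)
            sce_results[comp] = res.to_dict()
        _dump(sce_results, out / "sce_anova.json", config)
        artifacts["sce_anova"] = str(out / "sce_anova.json")

    # --- diffusion decomposition -----------------------------------------
    if "ddm" in config.arms:
        # the diffusion likelihood needs correct AND error RTs: clean on
        # the accuracy track (coil + missed only); slow outliers are the
        # contaminant mixture's job
        tms_ddm, rep_ddm = cl.clean_tms(tms, for_rt=False,
                                        coil_threshold=config.coil_threshold_mm)
        _dump(rep_ddm.to_dict(), out / "cleaning_tms_ddm.json", config)
        fcfg = FitConfig(p_c=config.fit_p_c, min_trials=config.fit_min_trials,
                         n_restarts=config.fit_restarts, fatol=config.fit_tol,
                         xatol=config.fit_tol, seed=config.seed)
        fits = fit_all(tms_ddm, fcfg)
        fits.to_csv(out / "ddm_fits.csv", index=False)
        anova = drift_anova(fits)
        post = posthoc_drift(fits)
        _dump({"anova": anova.to_dict(), "posthoc": post.to_dict(orient="records")},
              out / "drift_inference.json", config)
        artifacts["ddm_fits"] = str(out / "ddm_fits.csv")
        artifacts["drift_inference"] = str(out / "drift_inference.json")
        inter = anova["congruency:stimulation"]
        report_lines += [
            "## Drift-rate inference",
            f"Congruency x Stimulation interaction: F({inter.df_num:.0f},{inter.df_den:.0f}) "
            f"= {inter.F:.2f}, p = {inter.p:.4g} (GG-corrected p = {inter.p_gg:.4g})",
            "",
        ]

    if "distance" in config.arms:
        res = st.distance_analysis(tms_clean)
        _dump(res.to_dict(), out / "distance_anova.json", config)
        artifacts["distance_anova"] = str(out / "distance_anova.json")

    if "covariates" in config.arms and covars is not None:
        per_p = (tms_clean.groupby(["participant_id", "stimulation"])["rt_s"]
                 .mean().mul(1000).unstack())
        eff = per_p.apply(lambda r: st.rtms_effect_percent(r["active"], r["sham"]), axis=1)
        merged = covars.set_index("participant_id")
        predictors = merged[["age", "intensity_pct_rmt", "scalp_cortex_mm",
                             "target_activation_t", "dist_to_reference_mm", "days_between"]]
        res = st.backward_regression(eff.reindex(predictors.index), predictors)
        res.extra["rtms_effect_pct"] = {k: float(v) for k, v in eff.items()}
        _dump(res.to_dict(), out / "covariate_regression.json", config)
        artifacts["covariate_regression"] = str(out / "covariate_regression.json")

    (out / "report.md").write_text("\n".join(report_lines) + "\n")
    artifacts["report"] = str(out / "report.md")
    return artifacts
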