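"""Run configuration and the stage-based pipeline driver.

A single structured YAML config describes a run; every stage writes its
artifacts (profile CSVs, PK summary tables, verification reports,
assessment tables) plus a run manifest (config hash, seed, package version)
into the output directory, so identical config + seed reproduces identical
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .compound import load_compound
from .doseopt import TRIMESTER_WEEKS, TherapeuticWindow, assess_regimen
from .errors import ConfigError
from .estimation import FitSpec, fit_parameters
from .evaluation import (
    compute_pk_metrics,
    coverage_check,
    morris_screening,
    verification_report,
)
from .fetoplacental import cord_to_maternal_ratio, simulate_pregnant_with_fetus
from .pbpk import DoseRegimen, SimulationSettings, simulate_individual
from .physiology import build_physiology
from .population import (
    DEFAULT_PHENOTYPE_FREQUENCIES,
    DEFAULT_PHENOTYPE_MULTIPLIERS,
    PopulationSpec,
    run_population,
)
from .sensitivity import default_morris_model, DEFAULT_MORRIS_RANGES
from .synthetic import RICH_SAMPLING_TIMES, ObservedDataset, generate_observed

STAGES = ("nonpregnant", "pregnant", "fetal", "phenotypes", "doseopt",
          "verify", "fit", "sensitivity", "synth")


class RegimenConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dose_mg: float = 10.0
    interval_h: float = 24.0
    n_doses: int = 10


class PopulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects_per_trial: int = 10
    n_trials: int = 10
    cv_map: Optional[dict[str, float]] = None


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    compound_file: Optional[str] = None
    physiology_overrides: dict[str, float] = Field(default_factory=dict)
    regimen: RegimenConfig = Field(default_factory=RegimenConfig)
    gw_list: list[float] = Field(default_factory=lambda: [0.0, 20.0, 35.0])
    phenotype_frequencies: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_FREQUENCIES))
    phenotype_multipliers: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_MULTIPLIERS))
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    window: dict[str, float] = Field(default_factory=dict)
    observed_file: Optional[str] = None
    output_dir: str = "gestpbpk_out"
    seed: int = 0
    log_level: Literal["DEBUG", "INFO", "WARNING"] = "INFO"

    @field_validator("gw_list")
    @classmethod
    def _gw_in_range(cls, v):
        for gw in v:
            if not 0 <= gw <= 40:
                raise ValueError(f"gestational week out of range: {gw}")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except Exception as exc:
            raise ConfigError(str(exc)) from exc

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, out: Path, stage: str) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "package_version": __version__,
        "config": cfg.model_dump(),
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(cfg: RunConfig, stage: str) -> dict:
    """Execute one pipeline stage; returns a dict of headline numbers."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    compound, fetal = load_compound(cfg.compound_file)
    regimen = DoseRegimen(cfg.regimen.dose_mg, cfg.regimen.interval_h, cfg.regimen.n_doses)
    settings = SimulationSettings()
    headline: dict = {}

    if stage in ("nonpregnant", "pregnant"):
        gws = [0.0] if stage == "nonpregnant" else cfg.gw_list
        rows = []
        for gw in gws:
            phys = build_physiology(gw, cfg.physiology_overrides)
            prof = simulate_individual(compound, phys, regimen, settings)
            prof.to_csv(out / f"profile_gw{gw:g}.csv")
            m = compute_pk_metrics(prof, regimen.interval)
            rows.append({"gw": gw, "dose_mg": regimen.dose, "cmax": m.c_max,
                         "tmax": m.t_max, "auc": m.auc, "cmin_ss": m.c_min_ss,
                         "cavg_ss": m.c_avg_ss})
        table = pd.DataFrame(rows)
        table.to_csv(out / f"pk_summary_{stage}.csv", index=False)
        headline = {"pk_summary": rows}

    elif stage == "fetal":
        gw = max(cfg.gw_list)
        phys = build_physiology(gw, cfg.physiology_overrides)
        prof = simulate_pregnant_with_fetus(compound, phys, regimen, settings, fetal)
        prof.to_csv(out / f"profile_fetal_gw{gw:g}.csv")
        headline = {"gw": gw,
                    "cord_to_maternal_ratio": cord_to_maternal_ratio(prof, regimen.interval)}

    elif stage == "phenotypes":
        spec = PopulationSpec(cfg.population.n_subjects_per_trial,
                              cfg.population.n_trials, seed=cfg.seed)
        rows = []
        for gw in cfg.gw_list:
            phys = build_physiology(gw, cfg.physiology_overrides)
            for ph, mult in cfg.phenotype_multipliers.items():
                from .population import PhenotypeSpec
                summary = run_population(spec, compound, regimen, physiology=phys,
                                         phenotypes=[PhenotypeSpec(ph, 1.0, mult)])
                rows.append({"gw": gw, "phenotype": ph,
                             "mean_auc": float(summary.subject_auc.mean()),
                             "mean_cmin": float(summary.subject_cmin.mean())})
        pd.DataFrame(rows).to_csv(out / "phenotype_summary.csv", index=False)
        headline = {"phenotype_summary": rows}

    elif stage == "doseopt":
        assessment = assess_regimen(
            compound, doses=(10.0, 20.0), gws=TRIMESTER_WEEKS,
            phenotype_multipliers=cfg.phenotype_multipliers,
            window=TherapeuticWindow(**cfg.window) if cfg.window else None,
            population=PopulationSpec(cfg.population.n_subjects_per_trial,
                                      cfg.population.n_trials, seed=cfg.seed),
        )
        assessment.to_csv(out / "dose_assessment.csv")
        headline = {"n_cells": len(assessment.table),
                    "classifications": assessment.table["classification"].value_counts().to_dict()}

    elif stage == "verify":
        if not cfg.observed_file:
            raise ConfigError("verify stage requires observed_file")
        observed = ObservedDataset.from_csv(cfg.observed_file)
        gw = float(observed.frame["gw"].iloc[0])
        dose = float(observed.frame["dose_mg"].iloc[0])
        phys = build_physiology(gw, cfg.physiology_overrides)
        reg = DoseRegimen(dose, cfg.regimen.interval_h, cfg.regimen.n_doses)
        spec = PopulationSpec(cfg.population.n_subjects_per_trial,
                              cfg.population.n_trials, seed=cfg.seed)
        summary = run_population(spec, compound, reg, physiology=phys)
        t_last = (reg.n_doses - 1) * reg.interval
        cov = coverage_check(observed.frame[observed.frame.site == "maternal"],
                             summary, time_offset=t_last)
        obs_m = observed.frame[observed.frame.site == "maternal"]
        obs_auc = float(np.trapezoid(
            obs_m.groupby("time_h")["conc_ng_per_ml"].mean(),
            obs_m.groupby("time_h")["conc_ng_per_ml"].mean().index))
        obs_cmax = float(obs_m.groupby("time_h")["conc_ng_per_ml"].mean().max())
        mask = summary.times >= t_last
        pred_t = summary.times[mask] - t_last
        pred_c = summary.mean[mask]
        pred_auc = float(np.trapezoid(
            np.interp(np.unique(obs_m.time_h), pred_t, pred_c), np.unique(obs_m.time_h)))
        pred_cmax = float(pred_c.max())
        report = verification_report(
            {"cmax": (pred_cmax, obs_cmax), "auc": (pred_auc, obs_auc)}, coverage=cov)
        report.to_frame().to_csv(out / "verification_report.csv", index=False)
        (out / "verification_report.txt").write_text(
            f"AAFE: {report.aafe:.3f} (acceptable: {report.aafe_acceptable})\n"
            f"coverage: {cov:.3f}\n"
            + "\n".join(f"{k}: ratio {v:.3f} acceptable {report.ratio_acceptable[k]}"
                        for k, v in report.prediction_ratios.items()) + "\n")
        headline = {"aafe": report.aafe, "coverage": cov,
                    "ratios": report.prediction_ratios}

    elif stage == "fit":
        if not cfg.observed_file:
            raise ConfigError("fit stage requires observed_file")
        observed = ObservedDataset.from_csv(cfg.observed_file)
        gw = float(observed.frame["gw"].iloc[0])
        dose = float(observed.frame["dose_mg"].iloc[0])
        phys = build_physiology(gw, cfg.physiology_overrides)
        reg = DoseRegimen(dose, cfg.regimen.interval_h, cfg.regimen.n_doses)
        result = fit_parameters(observed, compound, phys, reg,
                                FitSpec(seed=cfg.seed, n_restarts=20))
        result.restarts.to_csv(out / "fit_restarts.csv", index=False)
        (out / "fit_result.json").write_text(json.dumps(
            {"parameters": result.parameters, "objective": result.objective}, indent=2))
        headline = {"parameters": result.parameters, "objective": result.objective}

    elif stage == "sensitivity":
        model = default_morris_model(compound, cfg.physiology_overrides)
        res = morris_screening(model, DEFAULT_MORRIS_RANGES(compound),
                               r=20, seed=cfg.seed)
        res.to_frame().to_csv(out / "morris_mu_star.csv", index=False)
        headline = {"top3_cmax": sorted(res.top("cmax")),
                    "top3_auc": sorted(res.top("auc"))}

    elif stage == "synth":
        gw = cfg.gw_list[0]
        phys = build_physiology(gw, cfg.physiology_overrides)
        ds = generate_observed(
            compound, phys, regimen, sampling_times=RICH_SAMPLING_TIMES,
            noise_cv=0.15, n_subjects=25, seed=cfg.seed, population_cv={},
        )
        ds.to_csv(out / "synthetic_observed.csv")
        headline = {"n_records": len(ds)}

    _write_manifest(cfg, out, stage)
    (out / f"headline_{stage}.json").write_text(json.dumps(headline, indent=2, default=float))
    return headline
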