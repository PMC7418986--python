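"""End-to-end driver: simulate -> clean -> reconstruct -> index -> impute -> fit.

The pipeline is deterministic given a configuration (including its seed):
two runs with the same config write byte-identical outputs.  Each stage
logs its row counts; any stage failure is re-raised with the stage name.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import (
    complaint_imputation as ci,
    conflict_models as cm,
    food_index as fi,
    harvest_records as hr,
    io,
    reconstruction as rc,
    simulate as sim,
)

log = logging.getLogger("ursaconflict")


@dataclass
class PipelineConfig:
    """All pipeline tunables, defaulting to the study's stated settings."""

    outdir: str = "."
    seed: int = 0
    misreport_rate: float = 0.11
    plus_age: int = 3
    nonhunt_fraction: float = 0.35
    poplevel_threshold: float = 15_000
    policy_year: int = 1998
    reliable_offset: int = 2
    max_delta: float = 4.0
    model_set: int = 1
    anchor_years: tuple[int, ...] = ci.DEFAULT_ANCHOR_YEARS
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        sim_cfg = sim.SimConfig(**raw.pop("sim", {}))
        cfg = cls(**{**raw, "sim": sim_cfg})
        defaults = cls()
        for f in dataclasses.fields(cls):
            if f.name != "sim" and getattr(cfg, f.name) != getattr(defaults, f.name):
                log.info("config override: %s = %r", f.name, getattr(cfg, f.name))
        return cfg


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    truth: sim.SimTruth
    observed: sim.ObservedData
    corrected_harvest: pd.DataFrame
    reconstruction: rc.ReconstructionResult
    covariates: pd.DataFrame
    food: pd.Series
    food_categories: pd.Series
    complaints: pd.DataFrame
    kills: pd.DataFrame
    design: pd.DataFrame
    fits: list[cm.ModelFit]
    aicc_table: pd.DataFrame
    diagnostics: pd.DataFrame


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return out

        return wrapped

    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig):
    truth = sim.simulate_truth(config.sim)
    observed = sim.render_observables(truth, config.sim)
    log.info("simulate: %d individuals, %d years", len(truth.individuals), len(truth.years))
    return truth, observed


@_stage("clean")
def _clean(observed: sim.ObservedData, config: PipelineConfig):
    corrected = hr.correct_sex(observed.age_harvest, config.misreport_rate)
    harvest_by_year = corrected.groupby("year")["count"].sum().to_dict()
    kills = hr.build_prevkill(harvest_by_year, observed.nuisance_kills.to_dict())
    log.info("clean: %d harvest cells", len(corrected))
    return corrected, kills


@_stage("reconstruct")
def _reconstruct(corrected: pd.DataFrame, config: PipelineConfig):
    result = rc.reconstruct(
        corrected, plus_age=config.plus_age, reliable_offset=config.reliable_offset
    )
    result = rc.adjust_nonharvest(result, config.nonhunt_fraction)
    covariates = rc.derive_covariates(result, config.poplevel_threshold)
    log.info("reconstruct: %d reliable years", len(covariates))
    return result, covariates


@_stage("foodindex")
def _foodindex(observed: sim.ObservedData):
    food = fi.yearly_ratings(observed.food_survey)
    categories = fi.categorize_years(food)
    log.info("foodindex: %d years, mean %.1f", len(food), food.mean())
    return food, categories


@_stage("impute")
def _impute(observed: sim.ObservedData, config: PipelineConfig):
    anchors = ci.anchors_from_series(observed.complaints, config.anchor_years)
    trend = ci.fit_phone_trend(anchors)
    complaints = ci.impute_totals(observed.complaints, trend)
    log.info("impute: %d imputed years", int(complaints["imputed"].sum()))
    return complaints


@_stage("fit")
def _fit(
    covariates: pd.DataFrame,
    food: pd.Series,
    complaints: pd.DataFrame,
    kills: pd.DataFrame,
    config: PipelineConfig,
):
    design = cm.assemble_design(
        covariates, food, complaints, kills, config.model_set, config.policy_year
    )
    fits = [cm.fit_ols(design, f) for f in cm.candidate_formulas(config.model_set)]
    table = cm.akaike_table(fits)
    # diagnostics for the AICc-best model
    best_name = table.iloc[0]["model"]
    best = next(f for f in fits if f.name == best_name)
    acf = cm.acf_check(best.residuals)
    acf.insert(0, "model", best_name)
    if len(best.predictors) >= 2:
        vifs = cm.vif(design, best.predictors)
        acf["vif_max"] = float(vifs.max())
    log.info("fit: best model %s (adj R2 %.2f)", best_name, best.adj_r2)
    return design, fits, table, acf


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every stage in order and (optionally) write the interchange CSVs."""
    truth, observed = _simulate(config)
    corrected, kills = _clean(observed, config)
    recon, covariates = _reconstruct(corrected, config)
    food, categories = _foodindex(observed)
    complaints = _impute(observed, config)
    design, fits, table, diagnostics = _fit(covariates, food, complaints, kills, config)

    result = PipelineResult(
        truth=truth,
        observed=observed,
        corrected_harvest=corrected,
        reconstruction=recon,
        covariates=covariates,
        food=food,
        food_categories=categories,
        complaints=complaints,
        kills=kills,
        design=design,
        fits=fits,
        aicc_table=table,
        diagnostics=diagnostics,
    )
    if write:
        write_outputs(result, config)
    return result


def write_simulated_inputs(observed: sim.ObservedData, truth: sim.SimTruth, outdir: str | Path) -> None:
    """Write the four observable input CSVs plus the truth table."""
    outdir = Path(outdir)
    io.write_csv(observed.age_harvest, outdir / "age_harvest.csv")
    yearly = observed.complaints[["year", "onsite", "phone"]].copy()
    yearly["nuisance_kills"] = observed.nuisance_kills.to_numpy()
    io.write_csv(yearly, outdir / "yearly.csv")
    io.write_csv(observed.food_survey, outdir / "food_survey.csv")
    io.write_csv(truth.abundance, outdir / "truth.csv")


def write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    write_simulated_inputs(result.observed, result.truth, outdir)
    io.write_csv(result.reconstruction.pooled().rename(
        columns={"estimate": "estimate"}), outdir / "population.csv")
    io.write_csv(result.covariates, outdir / "covariates.csv")
    food = result.food.rename("rating").reset_index()
    food["category"] = result.food_categories.to_numpy()
    io.write_csv(food, outdir / "food_yearly.csv")
    io.write_csv(result.complaints, outdir / "complaints_imputed.csv")
    io.write_csv(result.aicc_table, outdir / "aicc_table.csv")
    io.write_csv(result.diagnostics, outdir / "diagnostics.csv")
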