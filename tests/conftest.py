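import numpy as np
import pandas as pd
import pytest

from ursaconflict import PipelineConfig, SimConfig, run_pipeline, simulate_truth


@pytest.fixture(scope="session")
def default_truth():
    """One default-condition simulated history, shared across tests."""
    return simulate_truth(SimConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full default pipeline run (simulate through model competition)."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(outdir=str(outdir), seed=11)
    return run_pipeline(cfg)


@pytest.fixture()
def toy_harvest_table():
    """Two-age, one-year table used for sex-correction arithmetic."""
    return pd.DataFrame(
        {
            "year": [1990] * 4,
            "sex": ["F", "F", "M", "M"],
            "age": [1, 2, 1, 2],
            "count": [50, 39, 60, 40],
        }
    )


def harvest_only_config(seed: int = 0, n0: int = 5000, years: int = 40) -> SimConfig:
    """Harvest is the only mortality and the final season takes every bear,
    so every cohort is extinct by the last data year and cohort summation
    must equal truth exactly."""
    # certain harvest at age 30 keeps every death inside the harvest record
    rates = (0.25,) * 30 + (1.0,)
    return SimConfig(
        start_year=1981,
        end_year=1981 + years - 1,
        initial_abundance=n0,
        birth_rate=0.6,
        natural_mortality=(0.0,),
        harvest_rate_base={"F": rates, "M": rates},
        harvest_effort=((0, 1.0), (years - 1, 1e9)),
        food_effect_on_harvest=1.0,
        sex_misreport_rate=0.0,
        complaint_noise_sd=0.0,
        seed=seed,
    )


def true_pre_hunt_tally(truth) -> pd.DataFrame:
    """Independent oracle: tally pre-hunt abundance from individual fates.

    The census falls between natural deaths and harvest, so an individual is
    alive pre-hunt in year y if born on or before y and it either survives
    past y, is harvested in y, or is censored.  Deliberately recomputed from
    the raw fate records, not from the simulator's census table.
    """
    ind = truth.individuals
    rows = []
    for year in truth.years:
        death = ind["death_year"].fillna(10**9).to_numpy(dtype=float)
        harvested_now = (death == year) & (ind["cause"].to_numpy() == "harvest")
        alive = (ind["birth_year"].to_numpy() <= year) & ((death > year) | harvested_now)
        sub = ind[alive]
        tally = (
            sub.assign(age=year - sub["birth_year"])
            .groupby(["sex", "age"])
            .size()
            .rename("count")
            .reset_index()
        )
        tally.insert(0, "year", year)
        rows.append(tally)
    return pd.concat(rows, ignore_index=True)
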