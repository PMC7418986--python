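"""Individual-based simulator for a hunted, age-structured bear population.

The simulator produces a known-truth population history together with every
observable the analysis pipeline consumes: age-at-harvest records (with sex
misreporting), a fall food survey, nuisance-kill counts, and yearly complaint
counts split into phone-handled and on-site-visited components.

The yearly cycle is fixed as births -> natural deaths -> pre-hunt census ->
harvest, so the recorded abundance is the pre-hunt population that cohort
reconstruction estimates.  Each individual's fate (harvest, natural death, or
censored at the end of the series) is recorded, which lets tests tally exact
truth instead of trusting any aggregate bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FEMALE = "F"
MALE = "M"

#: Default masked span: phone-handled complaints went unrecorded in
#: 1981-1995 except 1984-85.
DEFAULT_MASKED_YEARS: tuple[int, ...] = tuple(
    y for y in range(1981, 1996) if y not in (1984, 1985)
)

#: Generating condition for model-competition recovery experiments: the
#: threshold-augmented complaint model.  The POPLEVEL step (an extra ~400
#: complaints when the population tops the threshold) and the noise sd are
#: part of the study conditions, fixed by a design-stage power analysis.
TOP_MODEL_PREDICTORS: tuple[str, ...] = ("POP", "FOOD", "POLICY", "POPLEVEL")
TOP_MODEL_COEFFS: dict[str, float] = {
    "Intercept": 1400.0,
    "POP": 0.2,
    "FOOD": -30.0,
    "POLICY": -500.0,
    "POPLEVEL": 400.0,
}
TOP_MODEL_NOISE_SD: float = 150.0


def _age_rate(rates: Sequence[float], age: np.ndarray) -> np.ndarray:
    """Look up a per-age rate; the last list entry covers all older ages."""
    idx = np.minimum(age, len(rates) - 1)
    return np.asarray(rates, dtype=float)[idx]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic population and its observables.

    Defaults emulate a four-decade statewide series in which the population
    roughly doubles from ~10,000 and later nearly halves, natural-food
    ratings fluctuate around the low 60s with episodic failures, a
    complaint-handling policy change occurs in 1998, and complaints respond
    linearly to population, food and policy.
    """

    start_year: int = 1981
    end_year: int = 2019
    initial_abundance: int = 10_000
    #: expected cubs per adult female per year (annualised litter production)
    birth_rate: float = 0.85
    adult_age: int = 3
    #: natural mortality probability by age; last entry applies to older ages
    natural_mortality: tuple[float, ...] = (0.25, 0.15, 0.10, 0.08)
    #: baseline harvest probability by sex and age; last entry = older ages
    harvest_rate_base: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            FEMALE: (0.04, 0.10, 0.13, 0.14),
            MALE: (0.05, 0.13, 0.17, 0.18),
        }
    )
    #: year-offset -> multiplier on harvest rates; shapes the double-then-halve
    #: trajectory (low pressure while the population grows, heavy mid-series)
    harvest_effort: tuple[tuple[int, float], ...] = (
        (0, 0.32),
        (11, 1.00),
        (16, 1.55),
        (21, 0.80),
    )
    #: harvest-rate multiplier in poor-food years (baits more attractive)
    food_effect_on_harvest: float = 1.30
    food_mean: float = 64.0
    food_sd: float = 8.0
    #: probability a given year is a food failure (~every 5-6 years)
    food_failure_prob: float = 0.18
    food_failure_mean: float = 46.0
    food_failure_sd: float = 2.5
    #: ratings below this count as "poor" for the harvest multiplier
    food_poor_threshold: float = 52.0
    n_food_species: int = 14
    n_food_respondents: int = 25
    sex_misreport_rate: float = 0.11
    policy_change_year: int = 1998
    complaint_intercept: float = 1400.0
    complaint_beta_pop: float = 0.2
    complaint_beta_food: float = -30.0
    complaint_beta_policy: float = -500.0
    complaint_noise_sd: float = 150.0
    #: expected nuisance kills per complaint
    nuisance_kill_rate: float = 0.04
    phone_ref_year: int = 1984
    phone_frac_at_ref: float = 0.60
    phone_frac_slope: float = 0.0125
    #: "binomial" draws phone counts; "deterministic" applies the exact
    #: fraction (fractional counts), used for exact round-trip validation
    phone_split: str = "binomial"
    masked_years: tuple[int, ...] = DEFAULT_MASKED_YEARS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year - self.start_year + 1 < 5:
            raise ValueError("simulation span must cover at least 5 years")
        if self.initial_abundance < 0:
            raise ValueError("initial_abundance must be non-negative")
        for name in ("birth_rate", "food_effect_on_harvest"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        probs = list(self.natural_mortality)
        for rates in self.harvest_rate_base.values():
            probs.extend(rates)
        probs.extend(
            [self.sex_misreport_rate, self.food_failure_prob, self.nuisance_kill_rate]
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.phone_split not in ("binomial", "deterministic"):
            raise ValueError("phone_split must be 'binomial' or 'deterministic'")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def effort(self, year: int) -> float:
        """Harvest-effort multiplier in effect for a calendar year."""
        offset = year - self.start_year
        value = 1.0
        for start, mult in sorted(self.harvest_effort):
            if offset >= start:
                value = mult
        return value

    def phone_fraction(self, year: int | np.ndarray) -> np.ndarray:
        """Linear phone-handling fraction trend on calendar year."""
        return self.phone_frac_at_ref + self.phone_frac_slope * (
            np.asarray(year) - self.phone_ref_year
        )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Complete individual-level ground truth for one simulated history.

    ``expected_complaints`` is the noise-free linear predictor; observation
    noise is added when observables are rendered, so a zero noise standard
    deviation makes observed totals equal this series exactly.
    """

    #: columns: id, sex, birth_year, death_year (nullable), cause
    individuals: pd.DataFrame
    #: pre-hunt census: columns year, sex, age, count
    abundance: pd.DataFrame
    #: true yearly food rating (the survey estimates this noisily)
    food: pd.Series
    #: noise-free expected complaint count per year
    expected_complaints: pd.Series
    years: range
    truncated: bool = False

    def pre_hunt_total(self) -> pd.Series:
        """True total pre-hunt abundance by year."""
        return self.abundance.groupby("year")["count"].sum()

    def harvest_table(self) -> pd.DataFrame:
        """True (correctly sexed) age-at-harvest counts: year, sex, age, count."""
        ind = self.individuals
        h = ind[ind["cause"] == "harvest"].copy()
        h["year"] = h["death_year"].astype(int)
        h["age"] = h["year"] - h["birth_year"]
        return (
            h.groupby(["year", "sex", "age"])
            .size()
            .rename("count")
            .reset_index()
            .astype({"count": int})
        )


@dataclass
class ObservedData:
    """Every data stream the analysis pipeline sees, and nothing more."""

    #: columns year, sex, age, count -- sex as reported by hunters
    age_harvest: pd.DataFrame
    #: nuisance (conflict) kills by year
    nuisance_kills: pd.Series
    #: columns year, species, respondent, abundance, production
    food_survey: pd.DataFrame
    #: columns year, onsite, phone, total; phone/total NaN in masked years
    complaints: pd.DataFrame


def _initial_population(config: SimConfig, rng: np.random.Generator):
    """Seed the population with a geometric-ish standing age distribution."""
    n = config.initial_abundance
    sex = np.where(rng.random(n) < 0.5, FEMALE, MALE)
    # survivorship-weighted ages 0..20: crude stable distribution
    ages = np.arange(21)
    weights = 0.78**ages
    age = rng.choice(ages, size=n, p=weights / weights.sum())
    return sex, config.start_year - age


def _draw_food(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    years = np.array(config.years)
    failure = rng.random(len(years)) < config.food_failure_prob
    rating = rng.normal(config.food_mean, config.food_sd, len(years))
    rating[failure] = rng.normal(
        config.food_failure_mean, config.food_failure_sd, failure.sum()
    )
    return pd.Series(np.clip(rating, 5.0, 110.0), index=years, name="food")


def simulate_truth(config: SimConfig) -> SimTruth:
    """Run the individual-based population simulation.

    Returns the full fate record of every individual ever alive, the pre-hunt
    abundance census by year/sex/age, the true food-rating series and the
    noise-free expected complaint series.  Identical config (including seed)
    gives identical output.  If the population goes extinct the output is
    truncated at the last year with survivors and flagged, with a warning.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    food = _draw_food(config, rng)

    sex, birth_year = _initial_population(config, rng)
    sex_a = np.array(sex, dtype=object)
    birth_a = np.asarray(birth_year, dtype=int)
    alive = np.ones(len(sex_a), dtype=bool)
    death_a = np.full(len(sex_a), np.nan)
    cause_a = np.full(len(sex_a), "censored", dtype=object)

    census_rows = []
    truncated = False
    last_year = config.start_year

    for year in config.years:
        # births: Poisson around per-capita rate of adult females
        age_now = year - birth_a
        n_mothers = int(np.sum(alive & (sex_a == FEMALE) & (age_now >= config.adult_age)))
        n_births = int(rng.poisson(config.birth_rate * n_mothers)) if n_mothers else 0
        if n_births:
            cub_sex = np.where(rng.random(n_births) < 0.5, FEMALE, MALE)
            sex_a = np.concatenate([sex_a, cub_sex])
            birth_a = np.concatenate([birth_a, np.full(n_births, year)])
            alive = np.concatenate([alive, np.ones(n_births, dtype=bool)])
            death_a = np.concatenate([death_a, np.full(n_births, np.nan)])
            cause_a = np.concatenate([cause_a, np.full(n_births, "censored", dtype=object)])

        age = year - birth_a
        # natural mortality; nothing survives past age 30
        idx = np.flatnonzero(alive)
        m = _age_rate(config.natural_mortality, age[idx])
        m = np.where(age[idx] > 30, 1.0, m)
        died = idx[rng.random(len(idx)) < m]
        alive[died] = False
        death_a[died] = year
        cause_a[died] = "natural"

        # pre-hunt census
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            warnings.warn(
                f"population extinct before {year}; output truncated", stacklevel=2
            )
            truncated = True
            break
        census = (
            pd.DataFrame({"sex": sex_a[idx], "age": age[idx]})
            .groupby(["sex", "age"])
            .size()
            .rename("count")
            .reset_index()
        )
        census.insert(0, "year", year)
        census_rows.append(census)
        last_year = year

        # harvest
        poor = food.loc[year] < config.food_poor_threshold
        mult = config.effort(year) * (config.food_effect_on_harvest if poor else 1.0)
        h = np.empty(len(idx))
        for s, rates in config.harvest_rate_base.items():
            mask = sex_a[idx] == s
            h[mask] = _age_rate(rates, age[idx][mask])
        h = np.clip(h * mult, 0.0, 1.0)
        shot = idx[rng.random(len(idx)) < h]
        alive[shot] = False
        death_a[shot] = year
        cause_a[shot] = "harvest"

    individuals = pd.DataFrame(
        {
            "id": np.arange(len(sex_a)),
            "sex": sex_a,
            "birth_year": birth_a,
            "death_year": pd.array(
                [int(d) if np.isfinite(d) else pd.NA for d in death_a], dtype="Int64"
            ),
            "cause": cause_a,
        }
    )
    abundance = (
        pd.concat(census_rows, ignore_index=True)
        if census_rows
        else pd.DataFrame(columns=["year", "sex", "age", "count"])
    )
    years = range(config.start_year, last_year + 1)
    food = food.loc[list(years)]

    pop = abundance.groupby("year")["count"].sum().reindex(list(years), fill_value=0)
    policy = (pop.index >= config.policy_change_year).astype(float)
    expected = (
        config.complaint_intercept
        + config.complaint_beta_pop * pop.to_numpy(dtype=float)
        + config.complaint_beta_food * food.to_numpy()
        + config.complaint_beta_policy * policy
    )
    expected_complaints = pd.Series(expected, index=pop.index, name="expected_complaints")

    return SimTruth(
        individuals=individuals,
        abundance=abundance,
        food=food,
        expected_complaints=expected_complaints,
        years=years,
        truncated=truncated,
    )


def _render_food_survey(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-species, per-respondent 0-4 scores whose product-mean tracks truth.

    Scores are Binomial(4, q) with q chosen so the expected species score
    (abundance x production) equals the true yearly rating split evenly
    across species; the survey rating is then an unbiased, noisy estimate.
    """
    rows = []
    n_sp, n_resp = config.n_food_species, config.n_food_respondents
    for year, rating in truth.food.items():
        per_species = rating / n_sp
        q = np.clip(np.sqrt(max(per_species, 0.0)) / 4.0, 0.02, 0.98)
        abund = rng.binomial(4, q, size=(n_sp, n_resp))
        prod = rng.binomial(4, q, size=(n_sp, n_resp))
        sp_idx, resp_idx = np.meshgrid(
            np.arange(1, n_sp + 1), np.arange(1, n_resp + 1), indexing="ij"
        )
        rows.append(
            pd.DataFrame(
                {
                    "year": year,
                    "species": sp_idx.ravel(),
                    "respondent": resp_idx.ravel(),
                    "abundance": abund.ravel(),
                    "production": prod.ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def render_observables(truth: SimTruth, config: SimConfig) -> ObservedData:
    """Degrade the truth into the observable data streams.

    Harvested females are independently recorded as males with probability
    ``sex_misreport_rate`` (counts are conserved; only the sex label moves).
    Complaint totals are the expected series plus Gaussian noise, rounded and
    clipped at zero, then split phone/on-site by the phone-fraction trend;
    phone counts are removed for the configured masked years.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 1)))

    harvest = truth.harvest_table()
    # sex misreporting: relabel a binomial share of each female cell as male
    if config.sex_misreport_rate > 0 and not harvest.empty:
        fem = harvest["sex"] == FEMALE
        flipped = rng.binomial(
            harvest.loc[fem, "count"].to_numpy(), config.sex_misreport_rate
        )
        moved = harvest.loc[fem].copy()
        moved["count"] = flipped
        moved["sex"] = MALE
        harvest.loc[fem, "count"] -= flipped
        harvest = (
            pd.concat([harvest, moved[moved["count"] > 0]], ignore_index=True)
            .groupby(["year", "sex", "age"])["count"]
            .sum()
            .reset_index()
        )
    harvest = harvest.sort_values(["year", "sex", "age"]).reset_index(drop=True)

    years = list(truth.years)
    expected = truth.expected_complaints.to_numpy()
    if config.complaint_noise_sd > 0:
        noisy = expected + rng.normal(0.0, config.complaint_noise_sd, len(expected))
    else:
        noisy = expected.copy()
    if (noisy < 0).any():
        warnings.warn("negative expected complaints clipped at 0", stacklevel=2)
        noisy = np.clip(noisy, 0.0, None)

    frac = np.clip(config.phone_fraction(np.array(years)), 0.0, 0.98)
    if config.phone_split == "binomial":
        total = np.rint(noisy).astype(int).astype(float)
        phone = rng.binomial(total.astype(int), frac).astype(float)
    else:
        total = noisy
        phone = total * frac
    onsite = total - phone
    complaints = pd.DataFrame(
        {"year": years, "onsite": onsite, "phone": phone, "total": total}
    )
    masked = complaints["year"].isin(config.masked_years)
    complaints.loc[masked, ["phone", "total"]] = np.nan

    nuisance = pd.Series(
        rng.poisson(config.nuisance_kill_rate * np.clip(noisy, 0.0, None)),
        index=pd.Index(years, name="year"),
        name="nuisance_kills",
    )

    food_survey = _render_food_survey(truth, config, rng)
    return ObservedData(
        age_harvest=harvest,
        nuisance_kills=nuisance,
        food_survey=food_survey,
        complaints=complaints,
    )
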