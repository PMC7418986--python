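"""Cohort (virtual-population) reconstruction of pre-hunt abundance.

For each sex and birth cohort, the pre-hunt population at age ``a`` (in
calendar year ``cohort + a``) is the cohort's cumulative observed harvest at
ages >= ``a``: every reconstructed animal eventually appears in the harvest
record.  This is a minimum-population estimator — animals dying of other
causes are invisible — so a constant non-hunting-mortality share is applied
afterwards as a uniform scale-up that leaves the shape of the trajectory
unchanged.

Cohorts still alive at the end of the data window are only partially
observed, so the final years of the series are biased low; those years are
flagged unreliable and excluded from covariate output (two years by default,
matching the behaviour of a plus-group reconstruction with ages pooled at
3+).  The contract over the reliable span is trend fidelity, not absolute
abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harvest_records import validate_age_harvest
from .simulate import FEMALE

MAX_AGE = 30


@dataclass
class ReconstructionResult:
    """Reconstructed pre-hunt abundance with reliability bookkeeping.

    ``estimates`` keeps exact ages internally (needed for the 6+-year-old
    female tally); pooled reporting is a view via :meth:`pooled`.
    """

    #: columns year, sex, age (exact int), estimate
    estimates: pd.DataFrame
    plus_age: int
    first_year: int
    last_data_year: int
    reliable_offset: int
    nonhunt_fraction: float = 0.0

    @property
    def last_reliable_year(self) -> int:
        return self.last_data_year - self.reliable_offset

    def reliable_years(self) -> range:
        return range(self.first_year, self.last_reliable_year + 1)

    def is_reliable(self, year: int) -> bool:
        return self.first_year <= year <= self.last_reliable_year

    def pop_total(self) -> pd.Series:
        """POP: total reconstructed pre-hunt abundance by year (all years)."""
        return self.estimates.groupby("year")["estimate"].sum().rename("POP")

    def popf6(self, min_age: int = 6) -> pd.Series:
        """POPF6: reconstructed females aged >= ``min_age`` by year."""
        df = self.estimates
        sel = df[(df["sex"] == FEMALE) & (df["age"] >= min_age)]
        return (
            sel.groupby("year")["estimate"]
            .sum()
            .reindex(self.pop_total().index, fill_value=0.0)
            .rename("POPF6")
        )

    def pooled(self) -> pd.DataFrame:
        """Estimates with ages >= plus_age merged into a plus class."""
        df = self.estimates.copy()
        label = f"{self.plus_age}plus"
        df["ageclass"] = np.where(
            df["age"] >= self.plus_age, label, df["age"].astype(str)
        )
        return (
            df.groupby(["year", "sex", "ageclass"], as_index=False)["estimate"]
            .sum()
            .sort_values(["year", "sex", "ageclass"])
            .reset_index(drop=True)
        )


def reconstruct(
    table: pd.DataFrame, plus_age: int = 3, reliable_offset: int = 2
) -> ReconstructionResult:
    """Reconstruct pre-hunt abundance from an exact-age harvest table.

    Parameters
    ----------
    table:
        Tidy age-at-harvest counts (year, sex, age, count) with exact integer
        ages.  Counts may be fractional (post sex-correction).
    plus_age:
        Age at which the reported composition is pooled into a plus group.
    reliable_offset:
        Number of final data years flagged unreliable: with ages pooled at
        3+ the reconstruction supports estimates up to 2 years before the
        most recent harvest (data through 2019 -> estimates through 2017).
    """
    validate_age_harvest(table, exact_ages=True)
    if table.empty:
        raise ValueError("empty age-at-harvest table")
    df = table.copy()
    df["age"] = df["age"].astype(int)
    df["count"] = df["count"].astype(float)
    first_year = int(df["year"].min())
    last_year = int(df["year"].max())

    rows = []
    for sex, grp in df.groupby("sex"):
        grp = grp.assign(cohort=grp["year"] - grp["age"])
        for cohort, cg in grp.groupby("cohort"):
            max_age = min(MAX_AGE, last_year - cohort)
            ages = np.arange(0, max_age + 1)
            harvest = (
                cg.set_index("age")["count"].reindex(ages, fill_value=0.0).to_numpy()
            )
            # N(age a) = cohort harvest at ages >= a (reverse cumulative sum)
            n = harvest[::-1].cumsum()[::-1]
            years = cohort + ages
            keep = (years >= first_year) & (years <= last_year) & (n > 0)
            rows.append(
                pd.DataFrame(
                    {
                        "year": years[keep],
                        "sex": sex,
                        "age": ages[keep],
                        "estimate": n[keep],
                    }
                )
            )
    estimates = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["year", "sex", "age"])
        .reset_index(drop=True)
    )
    return ReconstructionResult(
        estimates=estimates,
        plus_age=plus_age,
        first_year=first_year,
        last_data_year=last_year,
        reliable_offset=reliable_offset,
    )


def adjust_nonharvest(
    result: ReconstructionResult, nonhunt_fraction: float = 0.35
) -> ReconstructionResult:
    """Scale estimates up for mortality the harvest record never sees.

    Cohort reconstruction counts only animals that eventually die by
    hunting.  If a fraction ``f`` of total mortality is non-hunting, the
    full population is the reconstructed one divided by (1 - f).  The
    adjustment is identical for every year, so year-to-year ratios — the
    quantity compared with complaint trends — are unchanged.
    """
    if not 0.0 <= nonhunt_fraction < 1.0:
        raise ValueError("nonhunt_fraction must lie in [0, 1)")
    est = result.estimates.copy()
    scale = 1.0 / (1.0 - nonhunt_fraction)
    est["estimate"] = est["estimate"] * scale
    return ReconstructionResult(
        estimates=est,
        plus_age=result.plus_age,
        first_year=result.first_year,
        last_data_year=result.last_data_year,
        reliable_offset=result.reliable_offset,
        nonhunt_fraction=nonhunt_fraction,
    )


def derive_covariates(
    result: ReconstructionResult,
    poplevel_threshold: float = 15_000,
    popf6_min_age: int = 6,
    popf6_extra_offset: int = 3,
) -> pd.DataFrame:
    """Yearly covariate rows over the reliable span.

    Emits POP (total), POPF6 (females aged >= 6) and POPLEVEL (1 if POP
    exceeds the threshold).  POPF6 depends on older cohorts being fully
    observed, so it is withheld (NaN) for ``popf6_extra_offset`` additional
    years at the end of the series — reproducing the shorter span of
    analyses that include the prime-age-female covariate.
    """
    pop = result.pop_total()
    popf6 = result.popf6(min_age=popf6_min_age)
    years = [y for y in pop.index if result.is_reliable(y)]
    out = pd.DataFrame(
        {
            "year": years,
            "POP": pop.loc[years].to_numpy(),
            "POPF6": popf6.loc[years].to_numpy(),
        }
    )
    out["POPLEVEL"] = (out["POP"] > poplevel_threshold).astype(int)
    popf6_last = result.last_reliable_year - popf6_extra_offset
    out.loc[out["year"] > popf6_last, "POPF6"] = np.nan
    return out
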