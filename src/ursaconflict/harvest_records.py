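"""Cleaning and restructuring of age-at-harvest records.

Age-at-harvest tables are tidy DataFrames with columns ``year``, ``sex``
("F"/"M"), ``age`` (exact age in years, or a pooled label such as "3plus"),
and ``count``.  Counts may become fractional after the sex-misreport
correction; downstream reconstruction operates on real-valued counts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import FEMALE, MALE

REQUIRED_COLUMNS = ("year", "sex", "age", "count")


def validate_age_harvest(table: pd.DataFrame, *, exact_ages: bool = False) -> None:
    """Check schema, non-negative counts, age bounds and key uniqueness."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"age-at-harvest table missing columns: {missing}")
    if (table["count"] < 0).any():
        bad = table.loc[table["count"] < 0].iloc[0]
        raise ValueError(f"negative harvest count at year {bad['year']}")
    if table.duplicated(subset=["year", "sex", "age"]).any():
        raise ValueError("duplicate (year, sex, age) keys in age-at-harvest table")
    if exact_ages:
        ages = pd.to_numeric(table["age"], errors="coerce")
        if ages.isna().any():
            raise ValueError("exact integer ages required (pooled labels found)")
        if (ages < 0).any() or (ages > 30).any():
            raise ValueError("ages must lie in 0-30")


def correct_sex(table: pd.DataFrame, misreport_rate: float) -> pd.DataFrame:
    """Correct harvest sex totals for females misreported as males.

    Hunters record some harvested females as males (but essentially never the
    reverse), so the reported female total F understates the truth.  The
    corrected female total is F' = F / (1 - r); the excess F' - F is removed
    from the male column, allocated across male age classes proportionally to
    that year's male age distribution (and added to the same female age
    classes, since the moved animals keep their ages).  Yearly grand totals
    are conserved exactly; corrected counts may be fractional.
    """
    if not 0.0 <= misreport_rate < 1.0:
        raise ValueError("misreport_rate must lie in [0, 1)")
    validate_age_harvest(table)
    if misreport_rate == 0.0:
        return table.copy()

    parts = []
    for year, grp in table.groupby("year"):
        f = grp.loc[grp["sex"] == FEMALE].set_index("age")["count"].astype(float)
        m = grp.loc[grp["sex"] == MALE].set_index("age")["count"].astype(float)
        f_total, m_total = f.sum(), m.sum()
        shift = f_total / (1.0 - misreport_rate) - f_total
        if shift > m_total + 1e-9:
            raise ValueError(
                f"year {year}: male harvest ({m_total:g}) cannot absorb "
                f"sex-correction shift ({shift:g})"
            )
        alloc = shift * m / m_total if m_total > 0 else m * 0.0
        new_m = m - alloc
        new_f = f.add(alloc, fill_value=0.0)
        for s, series in ((FEMALE, new_f), (MALE, new_m)):
            part = series.rename("count").reset_index()
            part.insert(0, "sex", s)
            part.insert(0, "year", year)
            parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["year", "sex", "age"], key=_age_sort_key).reset_index(
        drop=True
    )


def _age_sort_key(col: pd.Series) -> pd.Series:
    if col.name != "age":
        return col
    return pd.to_numeric(col.astype(str).str.replace("plus", ""), errors="coerce")


def pool_ages(table: pd.DataFrame, plus_age: int = 3) -> pd.DataFrame:
    """Merge all ages >= ``plus_age`` into a single plus-group class.

    The pooled class is labelled e.g. "3plus"; younger ages keep their exact
    labels (as strings).  Per-(year, sex) totals are conserved exactly.
    """
    if plus_age < 1:
        raise ValueError("plus_age must be >= 1")
    validate_age_harvest(table)
    out = table.copy()
    ages = pd.to_numeric(out["age"], errors="coerce")
    label = f"{plus_age}plus"
    out["age"] = np.where(ages >= plus_age, label, ages.astype("Int64").astype(str))
    return (
        out.groupby(["year", "sex", "age"], as_index=False)["count"]
        .sum()
        .sort_values(["year", "sex", "age"], key=_age_sort_key)
        .reset_index(drop=True)
    )


def build_prevkill(
    harvest_by_year: Mapping[int, float], nuisance_by_year: Mapping[int, float]
) -> pd.DataFrame:
    """Assemble the previous-year total human-caused kill covariate.

    PREVKILL(y) = harvest(y-1) + nuisance(y-1): the number of bears removed
    the previous year through hunter harvest or killing in conflict
    situations.  The first covered year has no PREVKILL and is excluded from
    regression rows.  Any missing year inside the overlapping span is an
    error; no gap-filling.
    """
    h = pd.Series(dict(harvest_by_year), dtype=float).sort_index()
    n = pd.Series(dict(nuisance_by_year), dtype=float).sort_index()
    first = max(h.index.min(), n.index.min())
    last = min(h.index.max(), n.index.max())
    if first > last:
        raise ValueError("harvest and nuisance series do not overlap")
    span = range(int(first), int(last) + 1)
    for y in span:
        if y not in h.index:
            raise ValueError(f"harvest series missing year {y}")
        if y not in n.index:
            raise ValueError(f"nuisance series missing year {y}")
    kill = (h.loc[list(span)] + n.loc[list(span)]).rename("kill")
    prev = kill.shift(1).rename("PREVKILL")
    out = pd.concat([kill, prev], axis=1)
    out.index.name = "year"
    return out.reset_index()
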