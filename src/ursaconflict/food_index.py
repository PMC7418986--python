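"""Yearly natural-food abundance index from categorical field surveys.

Observers rate each of 14 key fruit-producing species twice on a 0-4 scale
(absent to abundant): once for the abundance of the plants and once for
their fruit production.  The two scores are multiplied per respondent,
averaged over respondents to a per-species score in [0, 16], and the species
scores are summed to a yearly rating in [0, 224].  Years are then labelled
poor / normal / abundant, by empirical terciles unless fixed cutpoints are
supplied.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SURVEY_COLUMNS = ("year", "species", "respondent", "abundance", "production")
CATEGORIES = ("poor", "normal", "abundant")


def validate_survey(survey: pd.DataFrame) -> None:
    missing = [c for c in SURVEY_COLUMNS if c not in survey.columns]
    if missing:
        raise ValueError(f"food survey missing columns: {missing}")
    for col in ("abundance", "production"):
        scores = survey[col]
        if ((scores < 0) | (scores > 4)).any():
            raise ValueError(f"{col} scores must lie in 0-4")


def species_score(survey: pd.DataFrame, year: int, species: int) -> float:
    """Respondent-averaged abundance x production score for one species."""
    validate_survey(survey)
    sel = survey[(survey["year"] == year) & (survey["species"] == species)]
    if sel.empty:
        raise ValueError(f"no respondents for species {species} in {year}")
    return float((sel["abundance"] * sel["production"]).mean())


def yearly_rating(
    survey: pd.DataFrame, year: int, species_ids: Sequence[int] | None = None
) -> float:
    """Sum of per-species scores for one year.

    All species in ``species_ids`` (default: every species present anywhere
    in the survey) must have at least one respondent that year; a missing
    species is an error, never silently imputed.
    """
    validate_survey(survey)
    if species_ids is None:
        species_ids = sorted(survey["species"].unique())
    sel = survey[survey["year"] == year]
    present = set(sel["species"].unique())
    absent = [s for s in species_ids if s not in present]
    if absent:
        raise ValueError(f"year {year}: no ratings for species {absent}")
    return float(sum(species_score(survey, year, s) for s in species_ids))


def yearly_ratings(
    survey: pd.DataFrame, species_ids: Sequence[int] | None = None
) -> pd.Series:
    """Yearly rating series over every surveyed year."""
    years = sorted(survey["year"].unique())
    return pd.Series(
        {y: yearly_rating(survey, y, species_ids) for y in years}, name="FOOD"
    ).rename_axis("year")


def categorize_years(
    ratings: Mapping[int, float] | pd.Series,
    method: str = "terciles",
    cutpoints: tuple[float, float] | None = None,
) -> pd.Series:
    """Label each year poor / normal / abundant.

    The default uses the empirical terciles of the observed rating
    distribution; explicit numeric ``cutpoints`` (lower, upper) override
    them, with rating < lower -> poor and rating >= upper -> abundant.
    Ratings falling exactly on a tercile boundary (including a fully
    degenerate all-equal distribution) resolve to "normal".
    """
    r = pd.Series(dict(ratings)).sort_index().astype(float)
    if cutpoints is not None:
        method = "fixed"
    if method == "terciles":
        if len(r) < 3:
            raise ValueError("need >= 3 years of ratings for empirical terciles")
        lo, hi = np.quantile(r.to_numpy(), [1 / 3, 2 / 3])
    elif method == "fixed":
        if cutpoints is None:
            raise ValueError("fixed method requires cutpoints")
        lo, hi = cutpoints
        if not lo < hi:
            raise ValueError("cutpoints must be strictly increasing")
    else:
        raise ValueError(f"unknown categorization method: {method}")
    labels = np.where(r < lo, "poor", np.where(r >= hi, "abundant", "normal"))
    if method == "terciles" and lo == hi:
        labels = np.full(len(r), "normal", dtype=object)
    return pd.Series(labels, index=r.index, name="category")
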