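"""Imputation of total complaints in years when only site visits were logged.

Early in the series the agency recorded a complaint only when staff visited
the site; phone-handled complaints went uncounted (by default 1981-83 and
1986-95).  The fraction of complaints handled by phone rose roughly linearly
over the years where both counts exist, so an ordinary least-squares line of
phone fraction on calendar year, fitted to the anchor years, predicts the
missing fraction p(y); the total is then onsite(y) / (1 - p(y)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Anchor spans with both phone and on-site counts recorded
DEFAULT_ANCHOR_YEARS: tuple[int, ...] = (1984, 1985, 1996, 1997, 1998)


@dataclass(frozen=True)
class PhoneTrend:
    """Fitted linear trend of phone-handled fraction on calendar year."""

    intercept: float
    slope: float
    logit: bool = False

    def predict(self, year: int | np.ndarray) -> np.ndarray:
        eta = self.intercept + self.slope * np.asarray(year, dtype=float)
        if self.logit:
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def fit_phone_trend(anchors: Mapping[int, float], logit: bool = False) -> PhoneTrend:
    """OLS line of phone fraction on calendar year through the anchor years.

    ``anchors`` maps year -> observed phone fraction.  At least two distinct
    years are required (the slope is otherwise undefined).  With
    ``logit=True`` the line is fitted on the log-odds scale instead; the
    straight-line fraction fit is the default.
    """
    years = np.array(sorted(anchors), dtype=float)
    if len(np.unique(years)) < 2:
        raise ValueError("need anchors in >= 2 distinct years to fit a trend")
    frac = np.array([anchors[int(y)] for y in years], dtype=float)
    if np.any((frac <= 0) | (frac >= 1)) and logit:
        raise ValueError("logit fit requires fractions strictly inside (0, 1)")
    y = np.log(frac / (1 - frac)) if logit else frac
    fit = sm.OLS(y, sm.add_constant(years)).fit()
    return PhoneTrend(
        intercept=float(fit.params[0]), slope=float(fit.params[1]), logit=logit
    )


def anchors_from_series(
    complaints: pd.DataFrame, anchor_years: Iterable[int] = DEFAULT_ANCHOR_YEARS
) -> dict[int, float]:
    """Observed phone fractions for the anchor years of a complaint table."""
    out = {}
    for year in anchor_years:
        row = complaints[complaints["year"] == year]
        if row.empty or row["phone"].isna().any():
            continue
        total = float(row["onsite"].iloc[0] + row["phone"].iloc[0])
        if total > 0:
            out[year] = float(row["phone"].iloc[0]) / total
    return out


def impute_totals(complaints: pd.DataFrame, trend: PhoneTrend) -> pd.DataFrame:
    """Fill total complaints for years where phone counts are absent.

    Input columns: year, onsite, phone (NaN where unrecorded).  For each
    masked year, total = onsite / (1 - p(y)) with p(y) from the fitted trend;
    a predicted fraction outside (0, 1) is an out-of-range extrapolation and
    raises.  Years with recorded phone counts are untouched (total = onsite
    + phone) and flagged ``imputed = 0``.
    """
    out = complaints.copy()
    masked = out["phone"].isna()
    p_hat = trend.predict(out.loc[masked, "year"].to_numpy())
    if np.any((p_hat <= 0) | (p_hat >= 1)):
        bad = out.loc[masked, "year"].to_numpy()[(p_hat <= 0) | (p_hat >= 1)]
        raise ValueError(
            f"predicted phone fraction outside (0, 1) for years {bad.tolist()}"
        )
    out["total"] = out["onsite"] + out["phone"]
    out.loc[masked, "total"] = out.loc[masked, "onsite"].to_numpy() / (1.0 - p_hat)
    out["imputed"] = masked.astype(int)
    bad = out["total"] < out["onsite"] - 1e-9
    if bad.any():
        raise ValueError("imputed total below on-site count (inconsistent inputs)")
    return out
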