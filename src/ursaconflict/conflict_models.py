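"""AICc competition of linear complaint models, with diagnostics.

Candidate models are ordinary least-squares regressions of yearly complaint
counts on subsets of: reconstructed population size (POP), the natural-food
rating (FOOD), previous-year human-caused kill (PREVKILL), the
complaint-handling policy indicator (POLICY), and either a population-level
threshold indicator (POPLEVEL, model set 1) or the count of prime-age
(6+-year-old) females (POPF6, model set 2).

Model scoring follows the small-sample information-theoretic convention:

    AICc  = -2 log L + 2k + 2k(k+1)/(n-k-1),   k = slopes + intercept + 1

(the +1 counts the residual variance), with Gaussian maximum-likelihood
log L computed from the residual sum of squares.  Akaike weights are the
normalised exp(-Delta/2).  Supporting diagnostics — adjusted R^2, variance
inflation factors and the residual autocorrelation function with 95% bounds
— are computed from their explicit formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

RESPONSE = "COMPLAINTS"


def assemble_design(
    covariates: pd.DataFrame,
    food: pd.Series,
    complaints: pd.DataFrame,
    kills: pd.DataFrame,
    set_id: int,
    policy_year: int = 1998,
    span: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Align all yearly series into one regression-ready table.

    ``covariates`` is the reconstruction output (year, POP, POPF6,
    POPLEVEL); ``food`` a year-indexed rating series; ``complaints`` must
    carry a ``total`` column (imputation already applied); ``kills`` the
    PREVKILL table.  Set 1 keeps POPLEVEL and drops POPF6; set 2 the
    reverse.  The span defaults to the widest run of years where every
    required column is present; PREVKILL is undefined in the first data year,
    which therefore never enters.  Any interior gap is an error.
    """
    if set_id not in (1, 2):
        raise ValueError("set_id must be 1 or 2")
    df = covariates.set_index("year").copy()
    df["FOOD"] = pd.Series(food)
    df[RESPONSE] = complaints.set_index("year")["total"]
    df["PREVKILL"] = kills.set_index("year")["PREVKILL"]
    df["POLICY"] = (df.index >= policy_year).astype(int)
    cols = [RESPONSE, "POP", "FOOD", "PREVKILL", "POLICY"]
    cols.append("POPLEVEL" if set_id == 1 else "POPF6")
    df = df[cols]

    if span is None:
        ok = df.notna().all(axis=1)
        if not ok.any():
            raise ValueError("no year has all required series present")
        span = (int(df.index[ok].min()), int(df.index[ok].max()))
    lo, hi = span
    years = list(range(lo, hi + 1))
    missing = [y for y in years if y not in df.index]
    if missing:
        raise ValueError(f"design span has missing years: {missing}")
    out = df.loc[years]
    gaps = out.columns[out.isna().any()].tolist()
    if gaps:
        bad_years = out.index[out.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in {gaps} for years {bad_years}")
    return out.reset_index()


def candidate_formulas(set_id: int) -> list[tuple[str, ...]]:
    """Default candidate sets: every model keeps a population measure.

    Set 1: POP plus any subset of {FOOD, POLICY, PREVKILL, POPLEVEL}.
    Set 2: POP, POPF6 or both, plus any subset of {FOOD, POLICY, PREVKILL}.
    """
    extras = ["FOOD", "POLICY", "PREVKILL"]

    def subsets(items: Sequence[str]):
        return chain.from_iterable(
            combinations(items, r) for r in range(len(items) + 1)
        )

    if set_id == 1:
        return [("POP",) + s for s in subsets(extras + ["POPLEVEL"])]
    if set_id == 2:
        pops = [("POP",), ("POPF6",), ("POP", "POPF6")]
        return [p + s for p in pops for s in subsets(extras)]
    raise ValueError("set_id must be 1 or 2")


@dataclass
class ModelFit:
    """One fitted candidate model and its information-theoretic scores."""

    predictors: tuple[str, ...]
    params: pd.Series
    residuals: np.ndarray
    rss: float
    n: int
    r2: float
    adj_r2: float
    loglik: float = field(init=False)
    k: int = field(init=False)
    aicc: float = field(init=False)

    def __post_init__(self) -> None:
        # k = slopes + intercept + residual variance
        self.k = len(self.predictors) + 2
        sigma2 = self.rss / self.n
        self.loglik = -0.5 * self.n * (np.log(2 * np.pi * sigma2) + 1.0)
        denom = self.n - self.k - 1
        if denom <= 0:
            raise ValueError("AICc undefined: n - k - 1 <= 0")
        self.aicc = -2.0 * self.loglik + 2 * self.k + 2 * self.k * (self.k + 1) / denom

    @property
    def name(self) -> str:
        return " + ".join(self.predictors)


def fit_ols(design: pd.DataFrame, predictors: Sequence[str]) -> ModelFit:
    """Least-squares fit of COMPLAINTS on the given predictor subset."""
    predictors = tuple(predictors)
    y = design[RESPONSE].to_numpy(dtype=float)
    X = sm.add_constant(design[list(predictors)].to_numpy(dtype=float)) \
        if predictors else np.ones((len(y), 1))
    n, p_plus_1 = X.shape
    if n <= p_plus_1 + 1:
        raise ValueError("too few rows for this model")
    if np.linalg.matrix_rank(X) < p_plus_1:
        raise ValueError(f"rank-deficient design for {predictors}")
    res = sm.OLS(y, X).fit()
    rss = float(np.sum(res.resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    p = len(predictors)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return ModelFit(
        predictors=predictors,
        params=pd.Series(res.params, index=["Intercept", *predictors]),
        residuals=np.asarray(res.resid),
        rss=rss,
        n=n,
        r2=r2,
        adj_r2=adj_r2,
    )


def akaike_table(fits: Iterable[ModelFit], max_delta: float | None = None) -> pd.DataFrame:
    """Rank fitted models by AICc with Akaike and cumulative weights.

    All fits must share the same response rows (same n).  ``max_delta``
    filters the report to models with Delta AICc at or below the threshold
    (weights are still normalised over the full candidate set).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fitted models")
    if len({f.n for f in fits}) != 1:
        raise ValueError("candidate models fitted on differing response rows")
    tab = pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "AICc": [f.aicc for f in fits],
            "adj_R2": [f.adj_r2 for f in fits],
        }
    )
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    rel = np.exp(-0.5 * tab["dAICc"].to_numpy())
    tab["weight"] = rel / rel.sum()
    tab = tab.sort_values("AICc", kind="mergesort").reset_index(drop=True)
    tab["cum_weight"] = tab["weight"].cumsum()
    if max_delta is not None:
        tab = tab[tab["dAICc"] <= max_delta].reset_index(drop=True)
    return tab[["model", "k", "AICc", "dAICc", "weight", "cum_weight", "adj_R2"]]


def vif(design: pd.DataFrame, predictors: Sequence[str]) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from regressing predictor j on the other predictors (with
    intercept).  Perfect collinearity yields ``inf`` rather than raising.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    X = design[predictors].to_numpy(dtype=float)
    for j, name in enumerate(predictors):
        yj = X[:, j]
        others = sm.add_constant(np.delete(X, j, axis=1))
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = np.sum((yj - yj.mean()) ** 2)
        r2j = 1.0 - np.sum(resid**2) / tss if tss > 0 else 1.0
        out[name] = np.inf if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
    return pd.Series(out, name="VIF")


def acf_check(residuals: np.ndarray, max_lag: int = 5) -> pd.DataFrame:
    """Residual autocorrelation with approximate 95% significance bounds.

    r_h = sum (e_t - e_bar)(e_{t+h} - e_bar) / sum (e_t - e_bar)^2, with
    bounds +-1.96/sqrt(n); ``within_bounds`` flags lags whose autocorrelation
    is consistent with white noise.
    """
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    if n < 5:
        raise ValueError("need >= 5 residuals for an ACF check")
    d = e - e.mean()
    denom = float(np.sum(d**2))
    if denom == 0:
        raise ValueError("constant residuals: ACF undefined")
    bound = 1.96 / np.sqrt(n)
    rows = []
    for h in range(0, max_lag + 1):
        r = float(np.sum(d[: n - h] * d[h:]) / denom)
        rows.append(
            {"lag": h, "acf": r, "bound": bound, "within_bounds": abs(r) <= bound or h == 0}
        )
    return pd.DataFrame(rows)
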