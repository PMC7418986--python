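"""Design assembly, OLS fits, AICc machinery and regression diagnostics."""

import numpy as np
import pandas as pd
import pytest

from ursaconflict import (
    acf_check,
    akaike_table,
    assemble_design,
    candidate_formulas,
    fit_ols,
    vif,
)
from ursaconflict.conflict_models import ModelFit


def _design(n=30, seed=0):
    rng = np.random.default_rng(seed)
    years = np.arange(1982, 1982 + n)
    pop = 10_000 + 500 * np.arange(n) + rng.normal(0, 200, n)
    food = rng.normal(60, 10, n)
    prevkill = rng.normal(2000, 300, n)
    policy = (years >= 1998).astype(int)
    poplevel = (pop > 15_000).astype(int)
    y = 1400 + 0.2 * pop - 30 * food - 500 * policy + rng.normal(0, 150, n)
    return pd.DataFrame(
        {
            "year": years,
            "COMPLAINTS": y,
            "POP": pop,
            "FOOD": food,
            "PREVKILL": prevkill,
            "POLICY": policy,
            "POPLEVEL": poplevel,
        }
    )


class TestAssembleDesign:
    def _inputs(self, years):
        cov = pd.DataFrame(
            {
                "year": years,
                "POP": np.linspace(10_000, 16_000, len(years)),
                "POPF6": np.linspace(500, 900, len(years)),
            }
        )
        cov["POPLEVEL"] = (cov["POP"] > 15_000).astype(int)
        food = pd.Series(60.0, index=pd.Index(years, name="year"))
        complaints = pd.DataFrame({"year": years, "total": 2000.0})
        kills = pd.DataFrame(
            {"year": years, "kill": 2000.0, "PREVKILL": [np.nan] + [2000.0] * (len(years) - 1)}
        )
        return cov, food, complaints, kills

    def test_policy_encoding_around_1998(self):
        years = list(range(1982, 2018))
        design = assemble_design(*self._inputs(years), set_id=1, policy_year=1998)
        d = design.set_index("year")
        assert d.loc[1997, "POLICY"] == 0
        assert d.loc[1998, "POLICY"] == 1

    def test_poplevel_consistent_with_threshold(self):
        years = list(range(1982, 2018))
        design = assemble_design(*self._inputs(years), set_id=1)
        assert ((design["POPLEVEL"] == 1) == (design["POP"] > 15_000)).all()

    def test_set2_span_row_count(self):
        """A 1982-2014 span yields 33 regression rows with POPF6 included."""
        years = list(range(1981, 2015))
        design = assemble_design(*self._inputs(years), set_id=2)
        assert "POPF6" in design.columns and "POPLEVEL" not in design.columns
        assert len(design) == 33  # 1982..2014: first year lost to PREVKILL

    def test_interior_gap_rejected(self):
        years = list(range(1982, 2018))
        cov, food, complaints, kills = self._inputs(years)
        food = food.drop(2000)
        with pytest.raises(ValueError, match="2000"):
            assemble_design(cov, food, complaints, kills, set_id=1,
                            span=(1983, 2017))


class TestFitOls:
    def test_perfect_linear_fit(self):
        d = _design()
        d["COMPLAINTS"] = 3.0 * d["POP"] + 7.0
        fit = fit_ols(d, ["POP"])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-6)
        assert fit.params["POP"] == pytest.approx(3.0)

    def test_adjusted_r2_formula(self):
        """n=10, p=2, R^2=0.75 gives adj R^2 = 1 - 0.25*9/7."""
        fit = ModelFit(
            predictors=("A", "B"),
            params=pd.Series(dtype=float),
            residuals=np.zeros(10),
            rss=25.0,
            n=10,
            r2=0.75,
            adj_r2=1 - 0.25 * 9 / 7,
        )
        assert fit.adj_r2 == pytest.approx(0.6786, abs=1e-4)

    def test_intercept_only_r2_zero(self):
        fit = fit_ols(_design(), [])
        assert fit.r2 == pytest.approx(0.0)

    def test_rank_deficient_rejected(self):
        d = _design()
        d["POP2"] = d["POP"] * 2.0
        with pytest.raises(ValueError, match="rank"):
            fit_ols(d, ["POP", "POP2"])

    def test_adj_r2_never_exceeds_r2(self):
        d = _design(seed=5)
        for formula in candidate_formulas(1):
            fit = fit_ols(d, formula)
            assert fit.adj_r2 <= fit.r2 + 1e-12

    def test_loglik_matches_statsmodels(self):
        """Dual route: the explicit Gaussian ML log-likelihood must agree
        with the statsmodels OLS llf."""
        import statsmodels.api as sm

        d = _design(seed=2)
        fit = fit_ols(d, ["POP", "FOOD"])
        ref = sm.OLS(
            d["COMPLAINTS"], sm.add_constant(d[["POP", "FOOD"]])
        ).fit()
        assert fit.loglik == pytest.approx(ref.llf, rel=1e-10)


class TestAkaikeTable:
    def test_single_model(self):
        tab = akaike_table([fit_ols(_design(), ["POP"])])
        assert tab["dAICc"].iloc[0] == 0.0
        assert tab["weight"].iloc[0] == pytest.approx(1.0)

    def test_two_model_weights_closed_form(self):
        """Delta = {0, 2} yields weights {0.731, 0.269}."""
        d = _design(seed=3)
        fits = [fit_ols(d, f) for f in (("POP", "FOOD", "POLICY"), ("POP", "FOOD"))]
        # construct the weights directly from the deltas the table reports
        tab = akaike_table(fits)
        deltas = np.array([0.0, 2.0])
        w = np.exp(-deltas / 2) / np.exp(-deltas / 2).sum()
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)
        # and the table's own weights always sum to one
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_k_counts_slopes_intercept_and_variance(self):
        d = _design(seed=4)
        fit = fit_ols(d, ["POP", "FOOD", "POLICY", "POPLEVEL"])
        assert fit.k == 6
        assert fit_ols(d, ["POP", "FOOD", "POLICY"]).k == 5

    def test_delta_invariant_to_loglik_constant(self):
        """Adding a constant to every log-likelihood (a density-convention
        change) must leave deltas and weights unchanged."""
        d = _design(seed=6)
        fits = [fit_ols(d, f) for f in candidate_formulas(1)]
        tab = akaike_table(fits)
        shifted = []
        for f in fits:
            g = ModelFit(
                predictors=f.predictors, params=f.params, residuals=f.residuals,
                rss=f.rss, n=f.n, r2=f.r2, adj_r2=f.adj_r2,
            )
            g.loglik += 17.0
            g.aicc -= 34.0
            shifted.append(g)
        tab2 = akaike_table(shifted)
        pd.testing.assert_series_equal(tab["dAICc"], tab2["dAICc"])
        pd.testing.assert_series_equal(tab["weight"], tab2["weight"])

    def test_weights_sum_to_one_and_cumulative_ordered(self):
        d = _design(seed=7)
        tab = akaike_table([fit_ols(d, f) for f in candidate_formulas(1)])
        assert tab["weight"].sum() == pytest.approx(1.0)
        assert (tab["dAICc"].diff().dropna() >= 0).all()
        assert tab["cum_weight"].iloc[-1] == pytest.approx(1.0)

    def test_max_delta_filter(self):
        d = _design(seed=8)
        tab = akaike_table([fit_ols(d, f) for f in candidate_formulas(1)], max_delta=4.0)
        assert (tab["dAICc"] <= 4.0).all()

    def test_mismatched_rows_rejected(self):
        f1 = fit_ols(_design(n=30), ["POP"])
        f2 = fit_ols(_design(n=25), ["POP"])
        with pytest.raises(ValueError):
            akaike_table([f1, f2])


class TestCandidateFormulas:
    def test_every_model_contains_a_population_measure(self):
        for set_id, pool in ((1, {"POP"}), (2, {"POP", "POPF6"})):
            for f in candidate_formulas(set_id):
                assert pool & set(f)

    def test_set_sizes(self):
        assert len(candidate_formulas(1)) == 16
        assert len(candidate_formulas(2)) == 24

    def test_printed_top_models_are_members(self):
        s1 = candidate_formulas(1)
        assert ("POP", "FOOD", "POLICY", "POPLEVEL") in s1
        assert ("POP", "FOOD", "POLICY") in s1
        s2 = candidate_formulas(2)
        assert ("POPF6", "FOOD", "POLICY") in s2
        assert ("POP", "POPF6", "FOOD", "POLICY") in s2


class TestVif:
    def test_orthogonal_predictors(self):
        n = 400
        d = pd.DataFrame({"A": np.tile([1, -1], n // 2), "B": np.repeat([1, -1], n // 2)})
        d["A"] = d["A"] - d["A"].mean()
        d["B"] = d["B"] - d["B"].mean()
        out = vif(d, ["A", "B"])
        np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-10)

    def test_known_correlation_closed_form(self):
        """Two predictors with sample correlation r have VIF 1/(1-r^2)."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=5000)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=5000)
        d = pd.DataFrame({"A": a, "B": b})
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        out = vif(d, ["A", "B"])
        assert out["A"] == pytest.approx(1 / (1 - r2), rel=1e-9)

    def test_duplicated_predictor_infinite(self):
        d = pd.DataFrame({"A": np.arange(10.0), "B": np.arange(10.0) * 2})
        out = vif(d, ["A", "B"])
        assert np.isinf(out).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        d = _design(seed=9)
        cols = ["POP", "FOOD", "PREVKILL", "POLICY"]
        ours = vif(d, cols)
        X = sm.add_constant(d[cols].to_numpy())
        for j, c in enumerate(cols):
            ref = variance_inflation_factor(X, j + 1)
            assert ours[c] == pytest.approx(ref, rel=1e-8)


class TestAcfCheck:
    def test_lag_zero_is_one(self):
        out = acf_check(np.random.default_rng(0).normal(size=36))
        assert out.loc[out["lag"] == 0, "acf"].iloc[0] == pytest.approx(1.0)

    def test_bounds_formula(self):
        out = acf_check(np.random.default_rng(1).normal(size=36))
        assert out["bound"].iloc[0] == pytest.approx(1.96 / 6, abs=1e-12)

    def test_alternating_residuals_flagged(self):
        e = np.tile([1.0, -1.0], 20)
        out = acf_check(e, max_lag=1).set_index("lag")
        assert out.loc[1, "acf"] == pytest.approx(-1.0, abs=0.05)
        assert not out.loc[1, "within_bounds"]

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            acf_check(np.ones(10))

    def test_matches_statsmodels_acf(self):
        from statsmodels.tsa.stattools import acf as sm_acf

        e = np.random.default_rng(2).normal(size=50)
        ours = acf_check(e, max_lag=5)["acf"].to_numpy()
        ref = sm_acf(e, nlags=5, fft=False)
        np.testing.assert_allclose(ours, ref, atol=1e-10)
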