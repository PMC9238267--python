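"""Wagstaff decomposition: adding-up identity, percentages, categories."""

import numpy as np
import pandas as pd
import pytest

from healthineq import (
    CollinearityError,
    WagstaffDecomposition,
    decompose_ci,
    fit_linear_additive_model,
    fractional_rank,
)
from healthineq.decomposition import CategoryMapError
from healthineq.ranking import _ci_value


def random_fixture(rng, n=200, k=3):
    """Regressors correlated with income rank plus a noisy linear outcome."""
    income = rng.exponential(size=n)
    ranked = fractional_rank(income)
    X = pd.DataFrame(
        {
            f"x{j}": 0.5 * j * ranked.ranks + rng.normal(size=n)
            for j in range(1, k + 1)
        }
    )
    beta = rng.normal(size=k)
    y = 1.0 + X.to_numpy() @ beta + 0.3 * rng.normal(size=n) + 2.0
    cats = {c: "economic" for c in X.columns}
    return y, X, ranked, cats


class TestLinearAdditiveModel:
    def test_exact_fit(self):
        x = np.linspace(0, 1, 50)
        y = 3.0 + 2.0 * x
        alpha, betas = fit_linear_additive_model(y, pd.DataFrame({"x": x}))
        assert alpha == pytest.approx(3.0, abs=1e-10)
        assert betas["x"] == pytest.approx(2.0, abs=1e-10)

    def test_recovery_with_noise(self, rng):
        n = 10_000
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = 0.5 + X["a"] * 1.5 - X["b"] * 0.7 + rng.normal(scale=0.5, size=n)
        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(X)).fit()
        alpha, betas = fit_linear_additive_model(y.to_numpy(), X)
        for name, truth in [("a", 1.5), ("b", -0.7)]:
            assert abs(betas[name] - truth) < 3 * fit.bse[name]

    def test_residuals_mean_zero(self, rng):
        y, X, _, _ = random_fixture(rng)
        alpha, betas = fit_linear_additive_model(y, X)
        resid = y - alpha - X.to_numpy() @ betas.to_numpy()
        assert abs(resid.mean()) < 1e-10

    def test_duplicated_column_raises(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = X["a"]
        with pytest.raises(CollinearityError, match="a|b"):
            fit_linear_additive_model(rng.normal(size=30), X)


class TestDecomposeCI:
    def test_single_regressor_identity(self):
        # y = x exactly: x's contribution is CI(x), residual 0, percent 100
        n = 100
        rng = np.random.default_rng(5)
        income = rng.exponential(size=n)
        ranked = fractional_rank(income)
        x = 1.0 + ranked.ranks
        dec = decompose_ci(x, pd.DataFrame({"x": x}), ranked, {"x": "economic"})
        assert dec.residual == pytest.approx(0.0, abs=1e-12)
        row = dec.table.loc["x"]
        assert row["contribution"] == pytest.approx(dec.total_ci, abs=1e-12)
        assert row["ck"] == pytest.approx(_ci_value(x, ranked.ranks), abs=1e-12)
        assert row["percent"] == pytest.approx(100.0, abs=1e-8)

    @pytest.mark.parametrize("trial", range(20))
    def test_adding_up_identity_randomized(self, trial):
        rng = np.random.default_rng(1000 + trial)
        y, X, ranked, cats = random_fixture(rng, n=150, k=4)
        dec = decompose_ci(y, X, ranked, cats)
        total_direct = _ci_value(np.asarray(y), ranked.ranks)
        assert dec.explained + dec.residual == pytest.approx(total_direct, abs=1e-10)
        if abs(dec.total_ci) > 1e-6:
            assert dec.table["percent"].sum() + dec.residual_percent == pytest.approx(
                100.0, abs=1e-6
            )

    def test_elasticity_definition(self, rng):
        y, X, ranked, cats = random_fixture(rng)
        dec = decompose_ci(y, X, ranked, cats)
        for name, row in dec.table.iterrows():
            assert row["elasticity"] == pytest.approx(
                row["beta"] * row["mean"] / dec.mean_y, abs=1e-12
            )

    def test_income_dominates_when_only_driver(self):
        # outcome depends on the rank alone; nuisance regressors are noise
        rng = np.random.default_rng(9)
        n = 50_000
        income = rng.exponential(size=n)
        ranked = fractional_rank(income)
        X = pd.DataFrame(
            {
                "rank_driver": ranked.ranks,
                "noise1": rng.normal(size=n) + 1.0,
                "noise2": rng.normal(size=n) + 1.0,
            }
        )
        y = 0.2 + 0.6 * ranked.ranks + 0.05 * rng.normal(size=n)
        cats = {c: "economic" for c in X.columns}
        dec = decompose_ci(y, X, ranked, cats)
        pct = dec.table["percent"].abs()
        assert pct["rank_driver"] == pct.max()
        assert dec.table.loc["rank_driver", "contribution"] > 0  # pro-rich driver

    def test_near_constant_regressor_contributes_nothing(self, rng):
        # near-constant limit: a perturbed constant column picks up no
        # share of the CI (its beta is absorbed by the intercept and its
        # covariance with the rank vanishes with the perturbation)
        n = 500
        income = rng.exponential(size=n)
        ranked = fractional_rank(income)
        noise = rng.normal(size=n)
        y = None
        contribs = []
        for scale in (1e-3, 1e-6, 1e-9):
            X = pd.DataFrame({"x": ranked.ranks, "c": 1.0 + scale * noise})
            y = 1.0 + X["x"].to_numpy()  # exactly linear in x
            dec = decompose_ci(y, X, ranked, {"x": "economic", "c": "economic"})
            contribs.append(abs(dec.table.loc["c", "contribution"]))
        assert all(c < 1e-8 for c in contribs)

    def test_tiny_total_ci_yields_nan_percent_with_warning(self):
        n = 2000
        rng = np.random.default_rng(3)
        income = rng.exponential(size=n)
        ranked = fractional_rank(income)
        X = pd.DataFrame({"x": rng.normal(size=n)})  # independent of rank
        y = 5.0 + 1e-9 * X["x"].to_numpy()
        with pytest.warns(RuntimeWarning, match="percentage"):
            dec = decompose_ci(y, X, ranked, {"x": "economic"})
        assert np.isnan(dec.table.loc["x", "percent"])
        assert np.isnan(dec.residual_percent)

    def test_unmapped_regressor_raises(self, rng):
        y, X, ranked, cats = random_fixture(rng)
        cats.pop("x1")
        with pytest.raises(CategoryMapError, match="x1"):
            decompose_ci(y, X, ranked, cats)

    def test_zero_mean_outcome_raises(self, rng):
        from healthineq import UndefinedIndexError

        n = 100
        ranked = fractional_rank(rng.exponential(size=n))
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = np.tile([1.0, -1.0], n // 2)  # exactly zero mean
        with pytest.raises(UndefinedIndexError):
            decompose_ci(y, X, ranked, {"x": "economic"})


class TestCategorySummary:
    def test_single_category_absorbs_everything(self, rng):
        y, X, ranked, cats = random_fixture(rng)
        dec = decompose_ci(y, X, ranked, cats)
        summ = dec.category_summary()
        assert summ.loc["economic", "contribution"] == pytest.approx(
            dec.total_ci - dec.residual, abs=1e-10
        )
        assert summ.loc["medical_distance", "contribution"] == 0.0

    def test_two_category_split_tracks_driver(self):
        rng = np.random.default_rng(21)
        n = 20_000
        income = rng.exponential(size=n)
        ranked = fractional_rank(income)
        X = pd.DataFrame({"driver": ranked.ranks, "other": rng.normal(size=n) + 1})
        y = 0.2 + 0.5 * ranked.ranks + 0.02 * rng.normal(size=n)
        dec = decompose_ci(y, X, ranked, {"driver": "economic", "other": "health"})
        summ = dec.category_summary()
        assert summ.loc["economic", "contribution"] == pytest.approx(
            dec.total_ci, rel=0.05
        )
        assert abs(summ.loc["health", "contribution"]) < 0.01 * abs(dec.total_ci) + 1e-4

    def test_from_dataframe_constructor(self, default_wave):
        dec = WagstaffDecomposition.from_dataframe(
            default_wave,
            "prevention",
            ["chronic_count", "srh", "adl", "iadl", "insurance_count"],
            rank_by="income",
        ).fit()
        assert dec.explained + dec.residual == pytest.approx(dec.total_ci, abs=1e-10)
        assert "Decomposition" in dec.summary()
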