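"""Wagstaff-style decomposition: LPM fit, covariate CIs, adding-up identity."""

import numpy as np
import pandas as pd
import pytest

from healthineq import (
    GeneratorConfig,
    contribution,
    covariate_ci,
    decompose,
    encode_covariates,
    erreygers_index,
    fit_lpm,
    fractional_rank,
    generate_dataset,
)
from healthineq.exceptions import ZeroMeanCovariateError
from healthineq.synthetic import DESIGN_COLUMNS


def _survey_arrays(ds, outcome="immunized", columns=DESIGN_COLUMNS):
    df = ds.df
    w = ds.weights
    r = fractional_rank(df["wealth_score"].to_numpy(), w)
    X = df[list(columns)].astype(float)
    return df[outcome].to_numpy(dtype=float), X, r, w, df["psu"].to_numpy()


class TestFitLpm:
    def test_single_binary_covariate_beta_is_mean_difference(self, rng):
        n = 400
        x = rng.integers(0, 2, size=n).astype(float)
        w = rng.uniform(0.5, 2.0, size=n)
        y = (rng.random(n) < 0.3 + 0.4 * x).astype(float)
        fit = fit_lpm(y, pd.DataFrame({"x": x}), w)
        diff = np.average(y[x == 1], weights=w[x == 1]) - np.average(y[x == 0], weights=w[x == 0])
        assert fit.params["x"] == pytest.approx(diff, abs=1e-12)

    def test_outcome_equal_to_covariate_fits_perfectly(self, rng):
        n = 200
        x1 = rng.integers(0, 2, size=n).astype(float)
        x2 = rng.normal(size=n)
        fit = fit_lpm(x1, pd.DataFrame({"x1": x1, "x2": x2}), np.ones(n))
        assert fit.params["x1"] == pytest.approx(1.0, abs=1e-10)
        assert fit.params["x2"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_bruteforce_normal_equations(self, small_survey):
        ds, _, _ = small_survey
        y, X, r, w, psu = _survey_arrays(ds)
        fit = fit_lpm(y, X, w, psu=psu)
        design = np.column_stack([np.ones(len(y)), X.to_numpy()])
        XtWX = design.T @ (design * w[:, None])
        XtWy = design.T @ (w * y)
        beta = np.linalg.solve(XtWX, XtWy)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_rank_deficiency_names_collinear_column(self, rng):
        n = 100
        x = rng.normal(size=n)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=n)})
        with pytest.raises(ValueError, match="b"):
            fit_lpm(rng.random(n), X, np.ones(n))


class TestCovariateCI:
    def test_rank_itself_has_ci_one_third(self):
        n = 10_000
        r = (np.arange(n) + 0.5) / n
        assert covariate_ci(r, r, np.ones(n)) == pytest.approx(1 / 3, abs=1e-3)

    def test_constant_covariate_has_zero_ci(self, rng):
        w = rng.uniform(0.5, 1.5, size=50)
        r = fractional_rank(rng.normal(size=50), w)
        assert covariate_ci(np.full(50, 3.0), r, w) == pytest.approx(0.0, abs=1e-15)

    def test_covariate_held_by_richest_is_pro_rich(self):
        n = 1000
        r = (np.arange(n) + 0.5) / n
        x = (r > 0.8).astype(float)
        assert covariate_ci(x, r, np.ones(n)) > 0

    def test_zero_mean_covariate_is_undefined(self, rng):
        w = np.ones(40)
        r = fractional_rank(rng.normal(size=40), w)
        x = np.concatenate([np.ones(20), -np.ones(20)])
        with pytest.raises(ZeroMeanCovariateError):
            covariate_ci(x, r, w)


class TestContributionIdentity:
    """The decomposition cell identity on published elasticity/CI pairs."""

    @pytest.mark.parametrize(
        "elasticity,ci_k,expected",
        [
            (0.0439, 0.2870, 0.0504),    # household wealth, immunization
            (-0.0616, 0.2405, -0.0593),  # mother's education, food security
            (-0.1391, 0.2870, -0.1597),  # household wealth, nutrition
            (-0.0226, -0.1719, 0.0155),  # birth order, immunization
        ],
    )
    def test_four_times_elasticity_times_ci(self, elasticity, ci_k, expected):
        assert contribution(elasticity, ci_k) == pytest.approx(expected, abs=5e-5)


class TestDecompose:
    def test_adding_up_identity_on_random_configs(self):
        """sum(contributions) + residual == ENCI to 1e-10, any generator."""
        rng = np.random.default_rng(99)
        for _ in range(12):
            cols = list(rng.choice(DESIGN_COLUMNS, size=5, replace=False))
            model = {"intercept": 0.3 + 0.3 * rng.random()}
            model.update({c: rng.normal(scale=0.04) for c in cols})
            cfg = GeneratorConfig(
                n_children=600, n_psu=40, outcome_models={"malnourished": model}
            )
            ds, _ = generate_dataset(cfg, seed=int(rng.integers(2**31)))
            y, X, r, w, psu = _survey_arrays(ds, "malnourished")
            res = decompose(y, X, r, w, psu=psu)
            assert res.check_adding_up(tol=1e-10)
            # residual equals 4x the generalized CI of the LPM error
            from healthineq.concentration import weighted_cov

            gc_resid = 8.0 * weighted_cov(res.lpm.resid, r, w)
            assert res.residual == pytest.approx(gc_resid, abs=1e-10)

    def test_outcome_independent_of_design_gives_null_contributions(self):
        cfg = GeneratorConfig(n_children=20_000, n_psu=400,
                              outcome_models={"malnourished": {"intercept": 0.4}})
        ds, _ = generate_dataset(cfg, seed=8)
        y, X, r, w, psu = _survey_arrays(ds, "malnourished")
        res = decompose(y, X, r, w, psu=psu)
        assert np.all(np.abs(res.table["contribution"]) < 0.01)
        assert res.residual == pytest.approx(res.enci - res.table["contribution"].sum(), abs=1e-12)

    def test_contributions_recover_population_truth(self):
        """Estimated contributions track 4 beta xbar CI_k from the oracle."""
        from healthineq import population_truth

        cfg = GeneratorConfig(n_children=8000, n_psu=200)
        truth = population_truth(cfg, oracle_n=200_000, seed=77)["malnourished"]
        ests = []
        for seed in range(30):
            ds, _ = generate_dataset(cfg, seed=seed)
            y, X, r, w, psu = _survey_arrays(ds, "malnourished")
            ests.append(decompose(y, X, r, w, psu=psu).table["contribution"].to_numpy())
        ests = np.asarray(ests)
        # 3 MC SEs per covariate plus a small allowance for testing all 13 at once
        for j, col in enumerate(DESIGN_COLUMNS):
            mc_se = ests[:, j].std(ddof=1) / np.sqrt(len(ests))
            assert abs(ests[:, j].mean() - truth["contributions"][col]) < 3 * mc_se + 1e-3

    def test_zero_mean_covariate_flagged_but_identity_holds(self, rng):
        n = 500
        wealth = rng.normal(size=n)
        w = np.ones(n)
        r = fractional_rank(wealth, w)
        x_zero = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        y = (rng.random(n) < 0.3 + 0.2 * (wealth > 0)).astype(float)
        X = pd.DataFrame({"sym": x_zero, "rich": (wealth > 0).astype(float)})
        res = decompose(y, X, r, w)
        assert np.isnan(res.table.loc["sym", "ci_k"])
        assert res.check_adding_up(tol=1e-10)
        assert any("sym" in note for note in res.notes)

    def test_near_zero_enci_suppresses_percentages(self, rng):
        n = 400
        w = np.ones(n)
        r = fractional_rank(rng.normal(size=n), w)
        y = np.ones(n)  # constant outcome: ENCI exactly 0
        X = pd.DataFrame({"x": rng.normal(size=n)})
        res = decompose(y, X, r, w)
        assert res.pct_suppressed
        assert res.table["pct"].isna().all()
        assert not np.isfinite(res.residual_pct)


class TestEncodeCovariates:
    def test_ordinal_encoding_single_column_per_covariate(self):
        df = pd.DataFrame({"edu": ["none", "primary", "secondary", "none"], "age": [20, 30, 40, 25]})
        X = encode_covariates(df, ["edu", "age"])
        assert list(X.columns) == ["edu", "age"]
        assert X["edu"].nunique() == 3

    def test_dummy_encoding_drops_reference_level(self):
        df = pd.DataFrame({"edu": ["a", "b", "c", "a"]})
        X = encode_covariates(df, ["edu"], encoding="dummy")
        assert list(X.columns) == ["edu[b]", "edu[c]"]
        np.testing.assert_array_equal(X.sum(axis=1).to_numpy(), [0, 1, 1, 0])
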