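"""Concentration index, Erreygers normalization, and clustered SEs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from healthineq import (
    GeneratorConfig,
    concentration_index,
    convenient_regression_index,
    erreygers_index,
    fractional_rank,
    generate_dataset,
    index_std_error,
)
from healthineq.exceptions import ClusterError, UndefinedIndexError


class TestConcentrationIndex:
    def test_constant_outcome_gives_zero(self, rng):
        w = rng.uniform(0.1, 2.0, size=50)
        r = fractional_rank(rng.normal(size=50), w)
        assert concentration_index(np.ones(50), r, w).value == 0.0

    def test_perfect_gradient_approaches_one_third(self):
        # h identical to the rank: CI = 2 var(r) / mean(r) -> 1/3
        n = 10_000
        r = (np.arange(n) + 0.5) / n
        est = concentration_index(r, r, np.ones(n))
        assert est.value == pytest.approx(1 / 3, abs=1e-3)

    def test_richest_half_only_approaches_half(self):
        n = 10_000
        r = (np.arange(n) + 0.5) / n
        h = (r > 0.5).astype(float)
        est = concentration_index(h, r, np.ones(n))
        assert est.value == pytest.approx(0.5, abs=1e-3)

    def test_zero_mean_outcome_undefined(self, rng):
        w = np.ones(10)
        r = fractional_rank(rng.normal(size=10), w)
        with pytest.raises(UndefinedIndexError):
            concentration_index(np.zeros(10), r, w)


class TestErreygers:
    def test_equal_distribution_gives_exact_zero(self, rng):
        w = rng.uniform(0.1, 3.0, size=200)
        r = fractional_rank(rng.normal(size=200), w)
        assert erreygers_index(np.ones(200), r, w).value == 0.0
        assert erreygers_index(np.full(200, 0.37), r, w).value == pytest.approx(0.0, abs=1e-15)

    def test_extreme_concentration_approaches_one(self):
        n = 10_000
        r = (np.arange(n) + 0.5) / n
        h = (r > 0.5).astype(float)
        est = erreygers_index(h, r, np.ones(n))
        assert est.value == pytest.approx(1.0, abs=0.01)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_mirror_property_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        w = rng.uniform(0.1, 2.0, size=n)
        r = fractional_rank(rng.normal(size=n), w)
        h = rng.integers(0, 2, size=n).astype(float)
        a = erreygers_index(h, r, w).value
        b = erreygers_index(1.0 - h, r, w).value
        assert a == pytest.approx(-b, abs=1e-12)

    def test_antisymmetric_under_wealth_reversal(self, rng):
        n = 150
        wealth = rng.normal(size=n)
        w = rng.uniform(0.1, 2.0, size=n)
        h = rng.integers(0, 2, size=n).astype(float)
        r = fractional_rank(wealth, w)
        r_rev = fractional_rank(-wealth, w)
        np.testing.assert_allclose(r_rev, 1.0 - r, atol=1e-12)
        assert erreygers_index(h, r_rev, w).value == pytest.approx(
            -erreygers_index(h, r, w).value, abs=1e-12
        )

    def test_bounds_scaling_matches_binary_special_case(self, rng):
        n = 100
        w = rng.uniform(0.5, 1.5, size=n)
        r = fractional_rank(rng.normal(size=n), w)
        h = rng.uniform(0, 1, size=n)
        # rescale to [2, 6]: ENCI is invariant to affine rescaling onto new bounds
        a = erreygers_index(h, r, w, bounds=(0, 1)).value
        b = erreygers_index(2 + 4 * h, r, w, bounds=(2, 6)).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_bounds_rejected(self, rng):
        w = np.ones(10)
        r = fractional_rank(rng.normal(size=10), w)
        with pytest.raises(ValueError):
            erreygers_index(np.ones(10), r, w, bounds=(1, 1))


class TestConvenientRegressionEquivalence:
    @pytest.mark.parametrize("estimator", ["CI", "ENCI"])
    def test_slope_equals_covariance_formula_100_datasets(self, estimator):
        """The two routes agree to 1e-10 on random weighted data."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(20, 300))
            wealth = rng.normal(size=n)
            w = rng.uniform(0.05, 4.0, size=n)
            r = fractional_rank(wealth, w)
            h = rng.integers(0, 2, size=n).astype(float)
            if h.sum() == 0:
                h[0] = 1.0
            direct = (
                concentration_index(h, r, w).value
                if estimator == "CI"
                else erreygers_index(h, r, w).value
            )
            slope = convenient_regression_index(h, r, w, estimator)
            assert abs(direct - slope) < 1e-10


class TestStandardErrors:
    def test_singleton_clusters_match_heteroskedasticity_robust(self, rng):
        n = 400
        wealth = rng.normal(size=n)
        w = rng.uniform(0.5, 1.5, size=n)
        r = fractional_rank(wealth, w)
        h = (rng.random(n) < 0.4 + 0.3 * r).astype(float)
        se_cluster = index_std_error(h, r, w, psu=np.arange(n))
        est = erreygers_index(h, r, w, psu=None)
        assert se_cluster == pytest.approx(est.std_error, rel=1e-8)

    def test_single_cluster_instructs_fallback(self, rng):
        n = 50
        w = np.ones(n)
        r = fractional_rank(rng.normal(size=n), w)
        h = rng.integers(0, 2, size=n).astype(float)
        with pytest.raises(ClusterError, match="psu=None"):
            index_std_error(h, r, w, psu=np.zeros(n))

    def test_cluster_se_within_15pct_of_cluster_bootstrap(self):
        """Sandwich SE vs a 1,000-replicate PSU bootstrap on clustered data."""
        cfg = GeneratorConfig(n_children=2000, n_psu=80, outcome_cluster_sd=0.08)
        ds, _ = generate_dataset(cfg, seed=11)
        df = ds.df
        h = df["malnourished"].to_numpy(dtype=float)
        w = ds.weights
        wealth = df["wealth_score"].to_numpy()
        psu = df["psu"].to_numpy()
        r = fractional_rank(wealth, w)
        se = index_std_error(h, r, w, psu=psu)

        rng = np.random.default_rng(5)
        clusters = np.unique(psu)
        idx_by_cluster = {c: np.where(psu == c)[0] for c in clusters}
        reps = np.empty(1000)
        for b in range(1000):
            chosen = rng.choice(clusters, size=clusters.size, replace=True)
            idx = np.concatenate([idx_by_cluster[c] for c in chosen])
            rb = fractional_rank(wealth[idx], w[idx])
            reps[b] = erreygers_index(h[idx], rb, w[idx]).value
        boot = reps.std(ddof=1)
        assert se == pytest.approx(boot, rel=0.15)

    def test_doubling_clusters_shrinks_se_by_sqrt2(self):
        """Duplicating every cluster (new ids) scales the SE by ~1/sqrt(2)."""
        cfg = GeneratorConfig(n_children=4000, n_psu=100, outcome_cluster_sd=0.05)
        ds, _ = generate_dataset(cfg, seed=21)
        df = ds.df
        h = df["immunized"].to_numpy(dtype=float)
        w = ds.weights
        wealth = df["wealth_score"].to_numpy()
        psu = df["psu"].to_numpy()
        r = fractional_rank(wealth, w)
        se1 = index_std_error(h, r, w, psu=psu)

        h2 = np.concatenate([h, h])
        w2 = np.concatenate([w, w])
        r2 = fractional_rank(np.concatenate([wealth, wealth]), w2)
        psu2 = np.concatenate([psu, psu + psu.max() + 1])
        se2 = index_std_error(h2, r2, w2, psu=psu2)
        assert se2 == pytest.approx(se1 / np.sqrt(2), rel=0.05)

    def test_parameter_recovery_within_3_mc_se(self):
        """Estimated ENCI is unbiased for the population truth (20 seeds)."""
        from healthineq import population_truth

        cfg = GeneratorConfig(n_children=5000, n_psu=200)
        truth = population_truth(cfg, oracle_n=100_000, seed=999)["immunized"]["enci"]
        vals = []
        for seed in range(20):
            ds, _ = generate_dataset(cfg, seed=seed)
            df = ds.df
            w = ds.weights
            r = fractional_rank(df["wealth_score"].to_numpy(), w)
            vals.append(erreygers_index(df["immunized"].to_numpy(dtype=float), r, w).value)
        vals = np.asarray(vals)
        mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - truth) < 3 * mc_se + 1e-9
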