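"""Rankings, elasticity regression, QQ curves, threshold summaries."""

import numpy as np
import pandas as pd
import pytest

from cobenefit import (
    ScenarioConfig,
    density_ratio_regression,
    generate_city_ratio_table,
    qq_cost_population,
    rank_entities,
    threshold_summary,
)


class TestRankings:
    def test_single_entity(self):
        df = pd.DataFrame({"entity": [0], "climate_cost_busd": [5.0], "integrated_cost_busd": [9.0]})
        out = rank_entities(df)
        assert out["rank_by_climate_cost"].iloc[0] == 1
        assert out["rank_by_integrated_cost"].iloc[0] == 1
        assert out["rank_shift"].iloc[0] == 0

    def test_climate_only_costs_identical_rankings(self):
        """With zero health valuation, integrated == climate cost and the two
        rankings coincide."""
        climate = [5.0, 2.0, 9.0, 1.0]
        df = pd.DataFrame({"entity": list("abcd"), "climate_cost_busd": climate,
                           "integrated_cost_busd": climate})
        out = rank_entities(df)
        assert (out["rank_shift"] == 0).all()

    def test_five_entity_brute_force_oracle(self):
        df = pd.DataFrame(
            {"entity": list("abcde"),
             "climate_cost_busd": [10.0, 40.0, 20.0, 5.0, 30.0],
             "integrated_cost_busd": [50.0, 45.0, 22.0, 60.0, 31.0]}
        )
        out = rank_entities(df).set_index("entity")
        # brute-force descending sort, ties by entity id
        exp_climate = sorted(df["entity"], key=lambda e: (-df.set_index("entity").loc[e, "climate_cost_busd"], e))
        exp_integrated = sorted(df["entity"], key=lambda e: (-df.set_index("entity").loc[e, "integrated_cost_busd"], e))
        for rank, e in enumerate(exp_climate, start=1):
            assert out.loc[e, "rank_by_climate_cost"] == rank
        for rank, e in enumerate(exp_integrated, start=1):
            assert out.loc[e, "rank_by_integrated_cost"] == rank
        assert (out["rank_shift"] == out["rank_by_climate_cost"] - out["rank_by_integrated_cost"]).all()

    def test_ranks_are_permutations(self, rng):
        n = 17
        df = pd.DataFrame({"entity": np.arange(n),
                           "climate_cost_busd": rng.random(n),
                           "integrated_cost_busd": rng.random(n)})
        out = rank_entities(df)
        for col in ("rank_by_climate_cost", "rank_by_integrated_cost"):
            assert sorted(out[col]) == list(range(1, n + 1))
        assert out["rank_shift"].sum() == 0  # shifts are antisymmetric in aggregate

    def test_predominant_subsector_shift(self):
        df = pd.DataFrame({"entity": ["p"], "climate_cost_busd": [10.0],
                           "integrated_cost_busd": [30.0]})
        sub = pd.DataFrame(
            {"entity": ["p", "p"], "subsector": [1, 2],
             "climate_cost_busd": [8.0, 2.0], "integrated_cost_busd": [10.0, 20.0]}
        )
        out = rank_entities(df, subsector_costs=sub)
        assert out["predominant_by_climate"].iloc[0] == 1
        assert out["predominant_by_integrated"].iloc[0] == 2
        assert bool(out["predominant_shifted"].iloc[0])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rank_entities(pd.DataFrame(columns=["entity", "climate_cost_busd", "integrated_cost_busd"]))


class TestDensityRatioRegression:
    def test_noiseless_planted_slope_recovered_exactly(self):
        cfg = ScenarioConfig(seed=21)
        cities = generate_city_ratio_table(cfg, n_cities=200, noise_sd=0.0)
        fits = density_ratio_regression(cities)
        for fit in fits.values():
            assert fit.slope == pytest.approx(cfg.planted_slope, abs=1e-10)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
            assert fit.ci_low <= fit.slope <= fit.ci_high

    def test_constant_ratio_zero_slope(self):
        cities = pd.DataFrame(
            {"population_density": np.logspace(1, 4, 30), "ratio": np.ones(30),
             "solid_fuel_fraction": np.full(30, 0.2)}
        )
        fit = density_ratio_regression(cities)["high_solid_fuel"]
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_nonpositive_cities_dropped_with_warning(self, caplog):
        cities = generate_city_ratio_table(ScenarioConfig(seed=2), n_cities=50, noise_sd=0.1)
        cities.loc[0, "ratio"] = 0.0
        with caplog.at_level("WARNING"):
            fits = density_ratio_regression(cities)
        assert "dropped 1" in caplog.text
        assert sum(f.n_cities for f in fits.values()) == 49

    def test_small_stratum_flagged(self):
        cities = pd.DataFrame(
            {"population_density": [10.0, 100.0, 50.0, 70.0, 90.0],
             "ratio": [0.5, 2.0, 1.0, 1.5, 1.8],
             "solid_fuel_fraction": [0.2, 0.2, 0.2, 0.005, 0.004]}
        )
        fits = density_ratio_regression(cities)
        assert fits["low_solid_fuel"].flagged
        assert not fits["high_solid_fuel"].flagged

    def test_ci_coverage_near_nominal(self):
        """95% CI covers the planted slope at roughly nominal frequency."""
        cfg = ScenarioConfig(seed=5)
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            cities = generate_city_ratio_table(cfg, n_cities=120, noise_sd=0.35, seed=1000 + rep)
            fit = density_ratio_regression(cities)["high_solid_fuel"]
            hits += fit.ci_low <= cfg.planted_slope <= fit.ci_high
        assert hits / n_rep >= 0.88


class TestQQCurve:
    def test_cost_proportional_to_population_is_diagonal(self, rng):
        pop = rng.random((6, 6))
        curve = qq_cost_population(3.3 * pop, pop)
        np.testing.assert_allclose(curve["cost_share"], curve["population_share"], atol=1e-12)

    def test_all_cost_in_most_populous_cell(self):
        pop = np.array([[10.0, 1.0], [2.0, 3.0]])
        cost = np.array([[7.0, 0.0], [0.0, 0.0]])
        curve = qq_cost_population(cost, pop)
        assert curve["cost_share"].iloc[1] == pytest.approx(1.0)
        assert curve["population_share"].iloc[1] == pytest.approx(10.0 / 16.0)

    def test_matches_brute_force_cumulative(self, rng):
        """10-cell random instance vs an independently coded cumulative scan."""
        pop = rng.random(10)
        cost = rng.random(10)
        curve = qq_cost_population(cost, pop)
        order = sorted(range(10), key=lambda k: (-pop[k], k))
        cum_p = cum_c = 0.0
        for step, k in enumerate(order, start=1):
            cum_p += pop[k] / pop.sum()
            cum_c += cost[k] / cost.sum()
            assert curve["population_share"].iloc[step] == pytest.approx(cum_p, rel=1e-12)
            assert curve["cost_share"].iloc[step] == pytest.approx(cum_c, rel=1e-12)

    def test_endpoints_and_monotonicity(self, rng):
        pop = rng.random((5, 5))
        cost = rng.random((5, 5))
        curve = qq_cost_population(cost, pop)
        assert curve.iloc[0].tolist() == [0.0, 0.0]
        assert curve["population_share"].iloc[-1] == pytest.approx(1.0)
        assert curve["cost_share"].iloc[-1] == pytest.approx(1.0)
        assert (np.diff(curve["population_share"]) >= -1e-15).all()
        assert (np.diff(curve["cost_share"]) >= -1e-15).all()

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            qq_cost_population(np.ones((2, 2)), np.zeros((2, 2)))


class TestThresholdSummary:
    def test_threshold_above_max(self, rng):
        cost = rng.random((4, 4))
        assert threshold_summary(cost, rng.random((4, 4)), threshold=10.0) == (0.0, 0.0)

    def test_tiny_threshold_all_positive(self, rng):
        cost = rng.random((4, 4)) + 0.1
        land, pop = threshold_summary(cost, rng.random((4, 4)), threshold=1e-12)
        assert (land, pop) == (1.0, 1.0)

    def test_matches_exhaustive_cell_scan(self, rng):
        cost = rng.random(20)
        pop = rng.random(20)
        thr = 0.5
        land, pshare = threshold_summary(cost, pop, thr)
        n_above = sum(1 for c in cost if c > thr)
        p_above = sum(p for c, p in zip(cost, pop) if c > thr)
        assert land == pytest.approx(n_above / 20)
        assert pshare == pytest.approx(p_above / pop.sum())
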