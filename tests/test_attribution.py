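"""Source attribution: weighted averaging, Eq.-style products, shares, ratios."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from cobenefit import (
    aggregate,
    attribute,
    co2_weighted_mean_ratio,
    contribution_ratio,
    monthly_weighted_sensitivity,
)
from cobenefit.attribution import AGGREGATION_LEVELS


class TestMonthlyWeightedSensitivity:
    def test_constant_sensitivity_unchanged(self, rng):
        S = np.full((5, 4), 3.7)
        E = rng.random((5, 4))
        np.testing.assert_allclose(monthly_weighted_sensitivity(S, E), np.full(4, 3.7))

    def test_zero_emission_fallback_unweighted(self, caplog):
        S = np.array([[1.0], [2.0], [3.0]])
        E = np.zeros((3, 1))
        with caplog.at_level("WARNING"):
            out = monthly_weighted_sensitivity(S, E)
        assert out[0] == pytest.approx(2.0)
        assert "unweighted" in caplog.text

    def test_three_day_hand_computed(self):
        S = np.array([2.0, 4.0, 10.0])
        E = np.array([1.0, 3.0, 6.0])
        expected = (2 * 1 + 4 * 3 + 10 * 6) / 10.0
        assert monthly_weighted_sensitivity(S, E) == pytest.approx(expected)

    def test_negative_emissions_rejected(self):
        with pytest.raises(ValueError):
            monthly_weighted_sensitivity(np.ones(3), np.array([1.0, -1.0, 2.0]))


def _toy_sensitivity(inventory, value=1.0):
    em = inventory["emissions"]
    return xr.DataArray(
        np.full((em.sizes["species"], em.sizes["month"], em.sizes["row"], em.sizes["col"]), value),
        dims=("species", "month", "row", "col"),
        coords={"species": em["species"].values, "month": em["month"].values},
    )


class TestAttribute:
    def test_zero_inventory(self, small_scenario):
        inventory = small_scenario[4].copy(deep=True)
        inventory["emissions"][:] = 0.0
        S = _toy_sensitivity(inventory, 2.0)
        assert float(attribute(S, inventory)["deaths"].sum()) == 0.0

    def test_single_cell_scalar_product(self):
        em = xr.Dataset(
            {
                "emissions": (("species", "month", "subsector", "row", "col"),
                              np.array([[[[[7.0]]]]])),
                "co2": (("month", "subsector", "row", "col"), np.array([[[[0.0]]]])),
            },
            coords={"species": ["OC"], "month": [1], "subsector": [0]},
        )
        S = xr.DataArray(np.array([[[[3.0]]]]), dims=("species", "month", "row", "col"),
                         coords={"species": ["OC"], "month": [1]})
        assert float(attribute(S, em)["deaths"].sum()) == pytest.approx(21.0)

    def test_linearity_in_subsector_sum(self, small_scenario):
        """sum_s M_{g,m,s} equals attribution of the subsector-summed inventory."""
        inventory = small_scenario[4]
        S = _toy_sensitivity(inventory, 1.3e-5)
        M = attribute(S, inventory)["deaths"]
        summed = inventory.copy(deep=True)
        collapsed = summed["emissions"].sum("subsector").expand_dims(subsector=[0]).transpose(
            "species", "month", "subsector", "row", "col"
        )
        one = xr.Dataset(
            {"emissions": collapsed,
             "co2": summed["co2"].sum("subsector").expand_dims(subsector=[0]).transpose(
                 "month", "subsector", "row", "col")},
        )
        M1 = attribute(S, one)["deaths"]
        np.testing.assert_allclose(M.sum("subsector").values, M1.sum("subsector").values, rtol=1e-12)

    def test_per_species_split_sums_to_total(self, small_scenario, rng):
        inventory = small_scenario[4]
        S = _toy_sensitivity(inventory, 1.0) * rng.random(
            (inventory.sizes["species"], 1, 1, 1))
        out = attribute(S, inventory, per_species=True)
        np.testing.assert_allclose(
            out["deaths_by_species"].sum("species").values, out["deaths"].values, rtol=1e-12
        )

    def test_misaligned_axes_rejected(self, small_scenario):
        inventory = small_scenario[4]
        S = _toy_sensitivity(inventory)[:, :6]  # truncate months
        with pytest.raises(ValueError):
            attribute(S, inventory)


@pytest.fixture(scope="module")
def small_attribution(small_scenario):
    inventory = small_scenario[4]
    S = _toy_sensitivity(inventory, 1.0)
    # modulate so the spatial pattern is nontrivial
    nr, nc = inventory.sizes["row"], inventory.sizes["col"]
    S = S * xr.DataArray(1 + np.arange(nr * nc).reshape(nr, nc) / (nr * nc), dims=("row", "col"))
    return attribute(S * 1e-5, inventory)


class TestAggregate:
    def test_shares_sum_to_100(self, small_scenario, small_attribution):
        _, regions, _, catalog, inventory = small_scenario[:5]
        for level in AGGREGATION_LEVELS:
            df = aggregate(small_attribution, inventory, level, regions=regions, catalog=catalog)
            assert df["death_share_pct"].sum() == pytest.approx(100.0, abs=1e-9)
            assert df["co2_share_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_group_partition(self, small_scenario, small_attribution):
        _, regions, _, catalog, inventory = small_scenario[:5]
        one = aggregate(small_attribution, inventory, "sector", catalog=catalog)
        collapsed = one[["deaths", "co2_t"]].sum()
        total_df = pd.DataFrame({"deaths": [collapsed["deaths"]], "co2_t": [collapsed["co2_t"]]})
        assert float(one["death_share_pct"].sum()) == pytest.approx(100.0)
        assert len(aggregate(small_attribution, inventory, "province", regions=regions)) > 1
        assert total_df["deaths"].iloc[0] == pytest.approx(float(small_attribution["deaths"].sum()))

    def test_subsector_shares_nest_in_sector_shares(self, small_scenario, small_attribution):
        _, regions, _, catalog, inventory = small_scenario[:5]
        sub = aggregate(small_attribution, inventory, "subsector", catalog=catalog)
        sec = aggregate(small_attribution, inventory, "sector", catalog=catalog)
        sector_of = catalog.sector_of()
        nested = sub.assign(sector=sub["entity"].map(sector_of)).groupby("sector")[
            "death_share_pct"
        ].sum()
        for _, row in sec.iterrows():
            assert nested[row["entity"]] == pytest.approx(row["death_share_pct"], abs=1e-9)

    def test_province_brute_force_oracle(self, small_scenario, small_attribution):
        """Grouped aggregation vs an exhaustive per-cell scan."""
        _, regions, _, _, inventory = small_scenario[:5]
        df = aggregate(small_attribution, inventory, "province", regions=regions)
        deaths_cell = small_attribution["deaths"].sum(("month", "subsector")).values
        co2_cell = inventory["co2"].sum(("month", "subsector")).values
        for _, row in df.iterrows():
            d = c = 0.0
            for i in range(deaths_cell.shape[0]):
                for j in range(deaths_cell.shape[1]):
                    if regions.province_of_cell[i, j] == row["entity"]:
                        d += deaths_cell[i, j]
                        c += co2_cell[i, j]
            assert row["deaths"] == pytest.approx(d, rel=1e-12)
            assert row["co2_t"] == pytest.approx(c, rel=1e-12)

    def test_missing_partition_rejected(self, small_scenario, small_attribution):
        inventory = small_scenario[4]
        with pytest.raises(ValueError):
            aggregate(small_attribution, inventory, "province")
        with pytest.raises(ValueError):
            aggregate(small_attribution, inventory, "nation")


class TestContributionRatio:
    def test_identical_patterns_unit_ratio(self):
        df = pd.DataFrame({"deaths": [10, 30.0], "co2_t": [100, 300.0],
                           "death_share_pct": [25.0, 75.0], "co2_share_pct": [25.0, 75.0]})
        out = contribution_ratio(df)
        np.testing.assert_allclose(out["ratio"], 1.0)

    def test_two_entity_arithmetic_oracle(self):
        df = pd.DataFrame({"deaths": [8, 2.0], "co2_t": [2, 8.0],
                           "death_share_pct": [80.0, 20.0], "co2_share_pct": [20.0, 80.0]})
        out = contribution_ratio(df)
        np.testing.assert_allclose(out["ratio"], [4.0, 0.25])
        assert co2_weighted_mean_ratio(out) == pytest.approx(1.0, abs=1e-12)

    def test_zero_co2_flagged_not_dropped(self):
        df = pd.DataFrame({"deaths": [5, 5.0], "co2_t": [10, 0.0],
                           "death_share_pct": [50.0, 50.0], "co2_share_pct": [100.0, 0.0]})
        out = contribution_ratio(df)
        assert out["zero_co2"].tolist() == [False, True]
        assert np.isnan(out.loc[1, "ratio"]) and len(out) == 2

    def test_weighted_mean_identity_all_levels(self, small_scenario, small_attribution):
        _, regions, _, catalog, inventory = small_scenario[:5]
        for level in ("grid", "city", "province"):
            df = contribution_ratio(
                aggregate(small_attribution, inventory, level, regions=regions, catalog=catalog)
            )
            assert co2_weighted_mean_ratio(df) == pytest.approx(1.0, abs=1e-12)
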