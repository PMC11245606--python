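"""Comparative statistics: rankings, elasticity regression, distribution curves.

These reproduce the analysis-layer statistics of the attribution study:
dual entity rankings under climate-only versus integrated cost with
predominant-subsector shift detection, the city-level log-log regression of
the health/CO2 contribution ratio on population density (stratified by
domestic solid-fuel dependence), quantile-quantile curves of cumulative cost
share against cumulative population share, and land/population shares of
cells above a cost threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    """ln(ratio) ~ ln(density) OLS fit for one solid-fuel stratum.

    ``slope`` is the elasticity: the % change in the contribution ratio per
    1% change in population density.
    """

    stratum: str
    slope: float
    intercept: float
    r_squared: float
    ci_low: float
    ci_high: float
    n_cities: int
    flagged: bool = False  # stratum below the minimum city count


def rank_entities(costs: pd.DataFrame,
                  subsector_costs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Dual rankings by climate-only and by integrated cost.

    ``costs`` needs ``entity``, ``climate_cost_busd``, ``integrated_cost_busd``.
    Ranks are dense descending (1 = largest), ties broken by entity
    identifier. ``rank_shift = rank_climate - rank_integrated`` (positive:
    the entity moves up once health damage is integrated). If
    ``subsector_costs`` (columns entity, subsector, climate_cost_busd,
    integrated_cost_busd) is given, the predominant subsector under each
    metric and the shift flag are attached.
    """
    if len(costs) == 0:
        raise ValueError("empty cost table")

    def dense_rank(df: pd.DataFrame, col: str) -> pd.Series:
        order = df.sort_values([col, "entity"], ascending=[False, True])["entity"]
        return pd.Series(np.arange(1, len(order) + 1), index=order)

    out = costs[["entity", "climate_cost_busd", "integrated_cost_busd"]].copy()
    rc = dense_rank(out, "climate_cost_busd")
    ri = dense_rank(out, "integrated_cost_busd")
    out["rank_by_climate_cost"] = out["entity"].map(rc)
    out["rank_by_integrated_cost"] = out["entity"].map(ri)
    out["rank_shift"] = out["rank_by_climate_cost"] - out["rank_by_integrated_cost"]
    if subsector_costs is not None:
        def predominant(col: str) -> pd.Series:
            return (
                subsector_costs.sort_values([col, "subsector"], ascending=[False, True])
                .groupby("entity", sort=False)["subsector"]
                .first()
            )

        out["predominant_by_climate"] = out["entity"].map(predominant("climate_cost_busd"))
        out["predominant_by_integrated"] = out["entity"].map(predominant("integrated_cost_busd"))
        out["predominant_shifted"] = out["predominant_by_climate"] != out["predominant_by_integrated"]
    return out


def density_ratio_regression(cities: pd.DataFrame, solid_fuel_threshold: float = 0.01,
                             min_cities: int = 3) -> dict[str, RegressionResult]:
    """Stratified OLS of ln(contribution ratio) on ln(population density).

    Cities are split at ``solid_fuel_threshold`` (default 1% of provincial
    energy use from domestic solid fuel). Nonpositive densities or ratios
    are dropped with a logged warning; a stratum below ``min_cities`` is
    fitted anyway but flagged. The 95% CI comes from the t-distribution of
    the OLS slope.
    """
    required = {"population_density", "ratio", "solid_fuel_fraction"}
    if not required.issubset(cities.columns):
        raise ValueError(f"city table must have columns {sorted(required)}")
    ok = (cities["population_density"] > 0) & (cities["ratio"] > 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("density_ratio_regression: dropped %d cities with nonpositive values", dropped)
    df = cities.loc[ok]
    strata = {
        "high_solid_fuel": df["solid_fuel_fraction"] > solid_fuel_threshold,
        "low_solid_fuel": df["solid_fuel_fraction"] <= solid_fuel_threshold,
    }
    results: dict[str, RegressionResult] = {}
    for name, mask in strata.items():
        sub = df.loc[mask]
        flagged = len(sub) < min_cities
        if len(sub) < 2:
            logger.warning("stratum %s has %d cities; regression skipped", name, len(sub))
            continue
        X = sm.add_constant(np.log(sub["population_density"].to_numpy()))
        fit = sm.OLS(np.log(sub["ratio"].to_numpy()), X).fit()
        ci = fit.conf_int(alpha=0.05)
        r2 = float(fit.rsquared)
        if not np.isfinite(r2):  # constant response: zero total sum of squares
            r2 = 0.0
        results[name] = RegressionResult(
            stratum=name,
            slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            r_squared=r2,
            ci_low=float(ci[1][0]),
            ci_high=float(ci[1][1]),
            n_cities=len(sub),
            flagged=flagged,
        )
    return results


def qq_cost_population(cost: np.ndarray, pop: np.ndarray) -> pd.DataFrame:
    """Cumulative cost share against cumulative population share.

    Cells are ordered by population (density, on the equal-area grid)
    descending, ties broken by cell index; the curve starts at (0, 0) and
    ends at (1, 1) and both coordinates are nondecreasing.
    """
    cost = np.asarray(cost, dtype=float).ravel()
    pop = np.asarray(pop, dtype=float).ravel()
    if cost.shape != pop.shape:
        raise ValueError("cost and population grids must be aligned")
    if pop.sum() <= 0:
        raise ValueError("all-zero population: the population axis is undefined")
    order = np.lexsort((np.arange(pop.size), -pop))
    pop_share = np.concatenate([[0.0], np.cumsum(pop[order]) / pop.sum()])
    total_cost = cost.sum()
    if total_cost > 0:
        cost_share = np.concatenate([[0.0], np.cumsum(cost[order]) / total_cost])
    else:
        cost_share = np.concatenate([[0.0], np.zeros(pop.size)])
    return pd.DataFrame({"population_share": pop_share, "cost_share": cost_share})


def threshold_summary(cost: np.ndarray, pop: np.ndarray, threshold: float) -> tuple[float, float]:
    """(land share, population share) of cells whose cost exceeds ``threshold``.

    Land share is a cell-count fraction — exact on the equal-area abstract
    grid; a projected grid would need area weighting.
    """
    cost = np.asarray(cost, dtype=float).ravel()
    pop = np.asarray(pop, dtype=float).ravel()
    if cost.shape != pop.shape:
        raise ValueError("cost and population grids must be aligned")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = cost > threshold
    land = above.sum() / cost.size
    pop_share = pop[above].sum() / pop.sum() if pop.sum() > 0 else 0.0
    return float(land), float(pop_share)
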