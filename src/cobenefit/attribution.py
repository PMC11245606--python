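"""Source attribution: sensitivities x subsector emissions, and ratio metrics.

The attributed health damage of subsector s in grid g and month m is the
first-order decomposition

    M_{g,m,s} = sum_p (dJ/dE_{p,g,m}) * dE_{p,g,m,s},

taking dE as the subsector's entire emission (marginal sensitivity times
total amount — not a zero-out re-simulation). Shares over any exhaustive
partition sum to 100%, and the contribution ratio of an entity is its share
of national health damage divided by its share of national CO2; the
CO2-share-weighted mean of the ratio is identically 1 over any partition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .domain import RegionPartition, SubsectorCatalog

logger = logging.getLogger(__name__)

AGGREGATION_LEVELS = ("sector", "subsector", "grid", "city", "province")


def monthly_weighted_sensitivity(daily_S: np.ndarray, daily_E: np.ndarray,
                                 axis: int = 0) -> np.ndarray:
    """Emission-weighted average of daily sensitivities over a month.

    S_bar = sum_d S_d E_d / sum_d E_d; where the month's emissions are all
    zero the unweighted mean is used (and logged), so constant sensitivities
    are returned unchanged under any weighting.
    """
    S = np.asarray(daily_S, dtype=float)
    E = np.asarray(daily_E, dtype=float)
    if S.shape != E.shape:
        raise ValueError(f"daily sensitivity {S.shape} and emission {E.shape} shapes differ")
    if (E < 0).any():
        raise ValueError("daily emissions must be nonnegative")
    wsum = E.sum(axis=axis)
    weighted = (S * E).sum(axis=axis)
    unweighted = S.mean(axis=axis)
    zero = wsum == 0
    if np.any(zero):
        logger.warning(
            "monthly_weighted_sensitivity: %d all-zero-emission slices fell back "
            "to the unweighted mean", int(np.count_nonzero(zero))
        )
    return np.where(zero, unweighted, weighted / np.where(zero, 1.0, wsum))


def attribute(sensitivity: xr.DataArray, inventory: xr.Dataset,
              per_species: bool = False) -> xr.Dataset:
    """Attribute deaths to subsectors: M_{g,m,s} = sum_p S_{p,g,m} dE_{p,g,m,s}.

    Linear in both factors, so subsector contributions superpose exactly.
    VOC-type species absent from the sensitivity field are ignored.
    """
    em = inventory["emissions"]
    common = [s for s in map(str, em["species"].values) if s in set(map(str, sensitivity["species"].values))]
    if not common:
        raise ValueError("no common species between sensitivity and inventory")
    for dim in ("month", "row", "col"):
        if em.sizes[dim] != sensitivity.sizes[dim]:
            raise ValueError(f"axis {dim!r} misaligned between sensitivity and inventory")
    prod = sensitivity.sel(species=common) * em.sel(species=common)
    out = xr.Dataset({"deaths": prod.sum("species")})
    if per_species:
        out["deaths_by_species"] = prod
    return out


def _share(values: np.ndarray) -> np.ndarray:
    total = values.sum()
    return 100.0 * values / total if total > 0 else np.zeros_like(values)


def aggregate(result: xr.Dataset, inventory: xr.Dataset, level: str,
              regions: RegionPartition | None = None,
              catalog: SubsectorCatalog | None = None) -> pd.DataFrame:
    """Absolute totals and percentage shares of deaths and CO2 per entity.

    ``level`` is one of sector, subsector, grid, city, province; region
    levels need ``regions``, sector needs ``catalog``. The grouping is
    exhaustive by construction (every cell/subsector belongs to exactly one
    entity), so shares sum to 100 exactly up to rounding.
    """
    if level not in AGGREGATION_LEVELS:
        raise ValueError(f"level must be one of {AGGREGATION_LEVELS}")
    deaths = result["deaths"]  # (month, subsector, row, col)
    co2 = inventory["co2"]

    if level in ("sector", "subsector"):
        d = deaths.sum(("month", "row", "col")).to_series()
        c = co2.sum(("month", "row", "col")).to_series()
        if level == "sector":
            if catalog is None:
                raise ValueError("sector aggregation requires the subsector catalog")
            sector_of = catalog.sector_of()
            if not set(d.index).issubset(set(sector_of.index)):
                raise ValueError("inventory subsectors missing from the catalog (non-exhaustive)")
            d = d.groupby(sector_of).sum()
            c = c.groupby(sector_of).sum()
        df = pd.DataFrame({"deaths": d, "co2_t": c})
        df.index.name = "entity"
    else:
        d_cell = deaths.sum(("month", "subsector")).values.ravel()
        c_cell = co2.sum(("month", "subsector")).values.ravel()
        if level == "grid":
            df = pd.DataFrame({"deaths": d_cell, "co2_t": c_cell})
            df.index.name = "entity"
        else:
            if regions is None:
                raise ValueError(f"{level} aggregation requires the region partition")
            labels = regions.labels(level).ravel()
            if labels.size != d_cell.size:
                raise ValueError("partition raster does not match the attribution grid")
            if (labels < 0).any():
                raise ValueError("partition is non-exhaustive: unlabeled cells present")
            n = labels.max() + 1
            df = pd.DataFrame(
                {
                    "deaths": np.bincount(labels, weights=d_cell, minlength=n),
                    "co2_t": np.bincount(labels, weights=c_cell, minlength=n),
                }
            )
            df.index.name = "entity"
    df["death_share_pct"] = _share(df["deaths"].to_numpy())
    df["co2_share_pct"] = _share(df["co2_t"].to_numpy())
    df["level"] = level
    return df.reset_index()


def contribution_ratio(shares: pd.DataFrame) -> pd.DataFrame:
    """Per-entity ratio of health-damage share to CO2 share.

    Entities with zero CO2 share get ratio NaN and ``zero_co2 = True``
    (flagged, not dropped). The CO2-share-weighted mean of the ratio over
    the partition equals 1 identically.
    """
    df = shares.copy()
    zero = df["co2_share_pct"] == 0
    df["ratio"] = np.where(zero, np.nan, df["death_share_pct"] / df["co2_share_pct"].where(~zero, 1.0))
    df["zero_co2"] = zero
    return df


def co2_weighted_mean_ratio(ratios: pd.DataFrame) -> float:
    """sum_e w_e r_e over defined ratios, w_e = the entity's CO2 share.

    Algebraically this equals the total death share (as a fraction) carried
    by entities with nonzero CO2 — exactly 1 over any partition in which
    every entity with health damage also emits CO2 (all spatial levels
    here); at subsector level the non-synergistic subsectors' death share is
    excluded, and the mean falls below 1 by exactly that share.
    """
    ok = ~ratios["zero_co2"]
    return float((ratios.loc[ok, "co2_share_pct"] / 100.0 * ratios.loc[ok, "ratio"]).sum())
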