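"""Monetization of health damage and CO2 climate damage (2011 US$).

Health damage is valued at a uniform value of statistical life (VSL) applied
to every entity — an explicit ethics convention — either set directly
(default 1.33 million US$ per death) or derived from the OECD benchmark by
benefit transfer,

    VSL_c = VSL_OECD * (Y_c / Y_OECD) ** e,

with income elasticity e. Climate damage is CO2 (tonnes) times the social
cost of carbon (SCC, US$/t; default 100 at a 2.5% discount rate). The
integrated cost of an entity is the exact sum of the two, in billion US$.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .config import ValuationConfig


def benefit_transfer_vsl(config: ValuationConfig) -> float:
    """VSL in million US$ via GDP-per-capita benefit transfer."""
    if config.y_c <= 0 or config.y_oecd <= 0:
        raise ValueError("GDP per capita must be positive")
    return config.vsl_oecd * (config.y_c / config.y_oecd) ** config.income_elasticity


def operative_vsl(config: ValuationConfig) -> float:
    """The uniform VSL actually applied: direct value or benefit transfer."""
    return config.vsl if config.vsl is not None else benefit_transfer_vsl(config)


def monetize(entities: pd.DataFrame, config: ValuationConfig,
             vsl: float | None = None, scc: float | None = None) -> pd.DataFrame:
    """Attach health, climate and integrated costs (billion US$) per entity.

    ``entities`` needs ``deaths`` and ``co2_t`` columns. deaths x VSL
    (million $) / 1000 and tonnes x SCC / 1e9 both land in billion $.
    """
    if not {"deaths", "co2_t"}.issubset(entities.columns):
        raise ValueError("entity table must have 'deaths' and 'co2_t' columns")
    if (entities["deaths"] < 0).any() or (entities["co2_t"] < 0).any():
        raise ValueError("deaths and CO2 must be nonnegative")
    vsl = operative_vsl(config) if vsl is None else vsl
    scc = config.scc if scc is None else scc
    out = entities.copy()
    out["health_cost_busd"] = out["deaths"] * vsl / 1.0e3
    out["climate_cost_busd"] = out["co2_t"] * scc / 1.0e9
    out["integrated_cost_busd"] = out["health_cost_busd"] + out["climate_cost_busd"]
    total = out["integrated_cost_busd"].sum()
    out["health_share"] = np.where(
        out["integrated_cost_busd"] > 0,
        out["health_cost_busd"] / out["integrated_cost_busd"].where(out["integrated_cost_busd"] > 0, 1.0),
        0.0,
    )
    out.attrs["vsl_musd"] = vsl
    out.attrs["scc_usd_per_t"] = scc
    out.attrs["total_integrated_busd"] = float(total)
    return out


def uncertainty_sweep(entities: pd.DataFrame, config: ValuationConfig,
                      scc_values: tuple[float, ...] | None = None) -> pd.DataFrame:
    """Re-monetize under {VSL_low, central, VSL_high} x an SCC grid.

    Returns a long table with ``vsl_case`` / ``scc`` columns; the central
    cell reproduces :func:`monetize` exactly. SCC moves climate cost only,
    so health-cost rankings are invariant across the SCC axis.
    """
    if scc_values is None:
        lo, hi = config.scc_range
        scc_values = tuple(sorted({lo, config.scc, hi}))
    if len(scc_values) == 0:
        raise ValueError("empty SCC grid")
    vsl_cases = {
        "low": config.vsl_low,
        "central": operative_vsl(config),
        "high": config.vsl_high,
    }
    frames = []
    for (case, vsl), scc in itertools.product(vsl_cases.items(), scc_values):
        df = monetize(entities, config, vsl=vsl, scc=scc)
        df["vsl_case"] = case
        df["vsl_musd"] = vsl
        df["scc"] = scc
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
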