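"""Seeded synthetic inputs with the structure the attribution analysis assumes.

Generates an abstract equal-area grid with a nested province/city partition,
a clustered population raster, a monthly speciated subsector emission
inventory with coupled CO2, exposure-response inputs, and monthly
meteorology for the transport surrogate. Each op draws from its own RNG
stream derived from the master seed, so (config, seed) bit-determines every
artifact and adding ops never perturbs existing draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .config import SECTORS, SPECIES, ConfigurationError, ScenarioConfig, substream
from .domain import DomainGrid, RegionPartition, SubsectorCatalog, build_catalog
from .health import BaselineMortality, IERParameters
from .transport import MeteorologyField


def generate_domain(config: ScenarioConfig) -> tuple[DomainGrid, RegionPartition]:
    """Grid plus nested province/city Voronoi partition.

    Provinces are Voronoi cells of random seed points; cities sub-partition
    each province the same way, so every grid cell carries exactly one city
    and one province and cities nest within provinces by construction. The
    city table carries a population density computed from the population
    field (regenerated here from its own stream, so it matches
    :func:`generate_population` exactly) and a solid-fuel usage fraction
    drawn per city: a low stratum below 1% of provincial energy use and a
    high stratum above it.
    """
    domain = DomainGrid(config.nrows, config.ncols, config.cell_size, config.mixing_height)
    rng = substream(config.seed, "domain")
    xg, yg = domain.cell_centers()
    pts = np.column_stack([xg.ravel(), yg.ravel()])

    def voronoi_labels(points: np.ndarray, n_seeds: int, gen: np.random.Generator) -> np.ndarray:
        lo, hi = points.min(axis=0), points.max(axis=0)
        seeds = gen.uniform(lo, hi, size=(n_seeds, 2))
        d = ((points[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)

    prov = voronoi_labels(pts, config.n_provinces, rng)
    # relabel to contiguous 0..P-1 (a seed point can lose every cell)
    prov = np.unique(prov, return_inverse=True)[1].reshape(domain.shape)

    city = np.full(domain.shape, -1, dtype=int)
    next_city = 0
    city_rows = []
    for p in range(int(prov.max()) + 1):
        mask = prov == p
        sub_pts = pts[mask.ravel()]
        k = min(config.cities_per_province, len(sub_pts))
        sub = voronoi_labels(sub_pts, k, rng)
        sub = np.unique(sub, return_inverse=True)[1]
        city[mask] = sub + next_city
        for c in range(int(sub.max()) + 1):
            city_rows.append({"city_id": next_city + c, "province_id": p})
        next_city += int(sub.max()) + 1

    pop = generate_population(domain, config)
    table = pd.DataFrame(city_rows)
    n_cells = np.bincount(city.ravel(), minlength=len(table))
    city_pop = np.bincount(city.ravel(), weights=pop.ravel(), minlength=len(table))
    table["n_cells"] = n_cells
    table["population"] = city_pop
    table["population_density"] = city_pop / (n_cells * domain.cell_area)
    low = rng.random(len(table)) < 0.4
    frac = np.where(low, rng.uniform(0.0, 0.01, len(table)), rng.uniform(0.01, 0.6, len(table)))
    table["solid_fuel_fraction"] = frac
    return domain, RegionPartition(prov, city, table)


def generate_population(domain: DomainGrid, config: ScenarioConfig) -> np.ndarray:
    """Clustered population raster, persons per cell.

    A lognormal rural background plus Gaussian city plumes whose peak
    density exceeds the background mean by ``cluster_contrast``; the field
    is rescaled to the configured national total.
    """
    rng = substream(config.seed, "population")
    nr, nc = domain.shape
    background = rng.lognormal(mean=0.0, sigma=config.pop_background_sigma, size=(nr, nc))
    n_clusters = config.n_provinces * config.cities_per_province
    if config.population_total == 0:
        return np.zeros((nr, nc))
    xg, yg = domain.cell_centers()
    field = background.copy()
    bg_mean = background.mean()
    for _ in range(n_clusters):
        cx = rng.uniform(0, nc * domain.cell_size)
        cy = rng.uniform(0, nr * domain.cell_size)
        w = config.cluster_width_cells * domain.cell_size
        bump = np.exp(-(((xg - cx) ** 2 + (yg - cy) ** 2) / (2 * w**2)))
        field += config.cluster_contrast * bg_mean * bump
    field *= config.population_total / field.sum()
    return field


def _spatial_pattern(domain: DomainGrid, pop: np.ndarray, rng: np.random.Generator,
                     population_weight: float) -> np.ndarray:
    """Normalized emission placement: population-tied mass plus a random field."""
    noise = rng.lognormal(mean=0.0, sigma=1.0, size=domain.shape)
    pop_part = pop / pop.sum() if pop.sum() > 0 else np.full(domain.shape, 1.0 / domain.n_cells)
    pattern = population_weight * pop_part + (1 - population_weight) * noise / noise.sum()
    return pattern / pattern.sum()


def _seasonal_weights(amplitude: float, peak_month: int) -> np.ndarray:
    """Monthly weights summing to 12, cosine-modulated around ``peak_month``."""
    m = np.arange(1, 13)
    w = 1.0 + amplitude * np.cos(2 * np.pi * (m - peak_month) / 12.0)
    return 12.0 * w / w.sum()


def generate_inventory(domain: DomainGrid, regions: RegionPartition,
                       catalog: SubsectorCatalog, config: ScenarioConfig,
                       pop: np.ndarray | None = None) -> xr.Dataset:
    """Monthly speciated subsector emissions with coupled CO2.

    Returns a Dataset with ``emissions`` (species, month, subsector, row,
    col; tonnes/month), ``co2`` (month, subsector, row, col; tonnes/month)
    and an ``apportionment`` table in ``attrs`` recording the within-sector
    subcategory fractions (which sum to one per sector).

    Species magnitudes per subsector come from Dirichlet-type profile draws
    biased toward carbonaceous primary PM for domestic solid-fuel
    subsectors, then each species is rescaled so national annual totals hit
    the configured targets. Domestic subsectors get a winter-peaked
    seasonality; CO2 follows each synergistic subsector's own spatial and
    seasonal pattern and is identically zero for non-synergistic ones.
    """
    rng = substream(config.seed, "inventory")
    if pop is None:
        pop = generate_population(domain, config)
    nsub = catalog.n_subsectors
    nr, nc = domain.shape

    # within-sector apportionment fractions (partition of unity per sector)
    apportion = np.empty(nsub)
    for sector in SECTORS:
        mask = (catalog.table["sector"] == sector).to_numpy()
        apportion[mask] = rng.dirichlet(np.full(mask.sum(), 2.0))
    # sector weights for the total pollutant mass
    sector_weight = {"energy": 0.18, "industrial": 0.30, "domestic": 0.30,
                     "transportation": 0.12, "agricultural": 0.10}
    sub_weight = np.array(
        [apportion[k] * sector_weight[catalog.table["sector"].iloc[k]] for k in range(nsub)]
    )

    # species profiles: Dirichlet draws, domestic solid fuel biased to OC/EC/PPM
    conc = np.full(len(SPECIES), config.dirichlet_concentration)
    profiles = np.empty((nsub, len(SPECIES)))
    dsf = catalog.table["domestic_solid_fuel"].to_numpy(dtype=bool)
    bias = conc.copy()
    bias[:3] *= 6.0  # OC, EC, PPM_other
    agri = (catalog.table["sector"] == "agricultural").to_numpy()
    nh3_bias = conc.copy()
    nh3_bias[SPECIES.index("NH3")] *= 12.0
    for k in range(nsub):
        c = bias if dsf[k] else (nh3_bias if agri[k] else conc)
        profiles[k] = rng.dirichlet(c)

    # unnormalized annual species mass per subsector, then per-species rescale
    mass = sub_weight[:, None] * profiles  # (subsector, species)
    target = np.array([config.species_totals[s] for s in SPECIES])
    col = mass.sum(axis=0)
    scale = np.divide(target, col, out=np.zeros_like(target), where=col > 0)
    mass = mass * scale[None, :]

    # spatial pattern and seasonality per subsector
    patterns = np.empty((nsub, nr, nc))
    seasons = np.empty((nsub, 12))
    sectors = catalog.table["sector"].to_numpy()
    for k in range(nsub):
        w = config.population_weight if sectors[k] in ("domestic", "transportation") else 0.4
        patterns[k] = _spatial_pattern(domain, pop, rng, w)
        if sectors[k] == "domestic":
            seasons[k] = _seasonal_weights(config.domestic_seasonal_amplitude, peak_month=1)
        else:
            phase = int(rng.integers(1, 13))
            seasons[k] = _seasonal_weights(config.seasonal_amplitude, peak_month=phase)

    em = (
        mass.T[:, None, :, None, None]  # (species, 1, subsector, 1, 1)
        * (seasons.T / 12.0)[None, :, :, None, None]
        * patterns[None, None, :, :, :]
    )

    # CO2: synergistic subsectors only, energy/industry-heavy split
    syn = catalog.synergistic_mask()
    co2_weight = np.where(syn, sub_weight, 0.0)
    sector_co2_boost = {"energy": 4.0, "industrial": 2.0, "domestic": 0.15,
                        "transportation": 1.0, "agricultural": 0.0}
    co2_weight = co2_weight * np.array([sector_co2_boost[s] for s in sectors])
    if co2_weight.sum() > 0:
        co2_annual = config.co2_total * co2_weight / co2_weight.sum()
    else:
        co2_annual = np.zeros(nsub)
    co2 = (
        co2_annual[None, :, None, None]
        * (seasons.T / 12.0)[:, :, None, None]
        * patterns[None, :, :, :]
    )

    ds = xr.Dataset(
        {
            "emissions": (("species", "month", "subsector", "row", "col"), em),
            "co2": (("month", "subsector", "row", "col"), co2),
        },
        coords={
            "species": list(SPECIES),
            "month": list(range(1, 13)),
            "subsector": catalog.subsector_ids,
        },
    )
    ds.attrs["apportionment"] = apportion.tolist()
    return ds


def generate_health_inputs(config: ScenarioConfig,
                           test_mode: bool = False) -> tuple[IERParameters, BaselineMortality]:
    """Exposure-response parameters and baseline mortality for five causes.

    Defaults are plausible rounded values in the range of the GBD IER fits;
    the table is configurable, not asserted as any particular published fit.
    ``test_mode`` permits alpha = 0 (RR identically 1 downstream).
    """
    params = IERParameters(z_cf=config.z_cf, allow_zero_alpha=test_mode)
    baseline = BaselineMortality(under5_fraction=config.under5_fraction)
    return params, baseline


def generate_meteorology(domain: DomainGrid, config: ScenarioConfig,
                         calm: bool = False) -> MeteorologyField:
    """Monthly winds, diffusivity and per-class loss rates.

    Wind direction rotates through the year with a smooth random
    perturbation; monthly mean speed matches ``config.wind_speed``. ``calm``
    zeroes the winds (diffusion/loss only).
    """
    rng = substream(config.seed, "meteorology")
    nr, nc = domain.shape
    if any(lam <= 0 for lam in config.loss_rates.values()):
        raise ConfigurationError("zero loss with zero-flux boundaries has no steady state")
    u = np.zeros((12, nr, nc))
    v = np.zeros((12, nr, nc))
    if not calm and config.wind_speed > 0:
        for m in range(12):
            theta = 2 * np.pi * m / 12.0 + rng.normal(0, 0.3)
            du = rng.normal(0, 0.1 * config.wind_speed, size=(nr, nc))
            dv = rng.normal(0, 0.1 * config.wind_speed, size=(nr, nc))
            uu = config.wind_speed * np.cos(theta) + du
            vv = config.wind_speed * np.sin(theta) + dv
            # rescale so the monthly mean speed matches the config exactly
            speed = np.sqrt(uu**2 + vv**2)
            factor = config.wind_speed / speed.mean()
            u[m], v[m] = uu * factor, vv * factor
    return MeteorologyField(
        u=u,
        v=v,
        diffusivity=np.full(12, config.diffusivity),
        loss_rates=dict(config.loss_rates),
    )


def generate_city_ratio_table(config: ScenarioConfig, n_cities: int = 300,
                              noise_sd: float | None = None,
                              seed: int | None = None) -> pd.DataFrame:
    """City table with a planted log-log density-ratio elasticity.

    ln(ratio) = ln(c) + slope * ln(density) + eps, eps ~ N(0, noise_sd^2);
    with ``noise_sd = 0`` the power law is exact and OLS recovers the
    planted slope with R^2 = 1. Used for regression-recovery and
    confidence-interval coverage studies.
    """
    if noise_sd is None:
        noise_sd = config.regression_noise_sd
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed if seed is None else seed), 89])
    )
    density = rng.lognormal(mean=5.0, sigma=1.2, size=n_cities)  # persons/km^2
    eps = rng.normal(0.0, noise_sd, size=n_cities) if noise_sd > 0 else np.zeros(n_cities)
    ratio = 0.8 * density**config.planted_slope * np.exp(eps)
    ratio /= ratio.mean()
    low = rng.random(n_cities) < 0.4
    frac = np.where(low, rng.uniform(0, 0.01, n_cities), rng.uniform(0.01, 0.6, n_cities))
    return pd.DataFrame(
        {
            "city_id": np.arange(n_cities),
            "population_density": density,
            "ratio": ratio,
            "solid_fuel_fraction": frac,
        }
    )


def generate_scenario(config: ScenarioConfig):
    """Convenience bundle: domain, regions, population, catalog, inventory,
    health inputs and meteorology for one seeded scenario."""
    domain, regions = generate_domain(config)
    pop = generate_population(domain, config)
    catalog = build_catalog(config.subsector_counts)
    inventory = generate_inventory(domain, regions, catalog, config, pop=pop)
    params, baseline = generate_health_inputs(config)
    met = generate_meteorology(domain, config)
    return domain, regions, pop, catalog, inventory, params, baseline, met
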