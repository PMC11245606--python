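"""Run configuration objects and YAML (de)serialization.

Every stochastic stage of the pipeline draws from a stream derived from the
single master seed in :class:`ScenarioConfig`, so a config fully determines
every generated artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

#: Emitted species carried by the inventory, in canonical order.
SPECIES: tuple[str, ...] = ("OC", "EC", "PPM_other", "SO2", "NOx", "NH3")

#: Sector names in canonical order.
SECTORS: tuple[str, ...] = (
    "energy",
    "industrial",
    "domestic",
    "transportation",
    "agricultural",
)

#: Disease-burden causes for the exposure-response model.
CAUSES: tuple[str, ...] = ("IHD", "stroke", "COPD", "lung_cancer", "ALRI")

# Fixed offsets deriving one independent RNG stream per generator op from the
# master seed; adding a new op must not perturb existing draws.
_STREAM_OFFSETS = {
    "domain": 11,
    "population": 23,
    "inventory": 37,
    "health": 53,
    "meteorology": 71,
    "city_table": 89,
    "probes": 101,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the dedicated RNG stream for generator op ``name``."""
    if name not in _STREAM_OFFSETS:
        raise KeyError(f"unknown RNG stream {name!r}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_OFFSETS[name]]))


class ConfigurationError(ValueError):
    """Raised when a config value violates a documented invariant."""


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic study domain.

    Defaults define the standard desk-scale scenario: a 40 x 40 equal-area
    grid of 36-km cells, 12 months, 53 subsectors split 6/24/15/5/3 across
    the energy, industrial, domestic, transportation and agricultural
    sectors, and a clustered population of 1.4 billion.
    """

    seed: int = 0
    nrows: int = 40
    ncols: int = 40
    cell_size: float = 36.0  # km
    mixing_height: float = 1.0  # km, converts surface emission to volume source

    n_provinces: int = 6
    cities_per_province: int = 3

    # population
    population_total: float = 1.4e9
    pop_background_sigma: float = 0.8  # lognormal sigma of the rural field
    cluster_contrast: float = 100.0  # city-core density over rural background
    cluster_width_cells: float = 1.2  # Gaussian radius of a city plume, cells

    # subsector catalog
    subsector_counts: tuple[int, ...] = (6, 24, 15, 5, 3)

    # emissions: national annual totals, tonnes/year per species
    species_totals: dict[str, float] = field(
        default_factory=lambda: {
            "OC": 2.0e6,
            "EC": 1.5e6,
            "PPM_other": 6.0e6,
            "SO2": 1.0e7,
            "NOx": 2.0e7,
            "NH3": 1.0e7,
        }
    )
    co2_total: float = 1.1e10  # tonnes/year across synergistic subsectors
    dirichlet_concentration: float = 2.0  # species-profile sharpness
    population_weight: float = 0.7  # share of a subsector's spatial pattern tied to population
    seasonal_amplitude: float = 0.25  # relative monthly modulation, non-domestic
    domestic_seasonal_amplitude: float = 0.6  # winter-heating modulation

    # health inputs
    z_cf: float = 5.8  # counterfactual PM2.5, ug/m3
    under5_fraction: float = 0.06  # population slice for ALRI

    # meteorology
    wind_speed: float = 10.0  # km/h monthly mean
    diffusivity: float = 50.0  # km^2/h
    loss_rates: dict[str, float] = field(
        default_factory=lambda: {
            "particle": 0.008,
            "SO2": 0.020,
            "NOx": 0.030,
            "NH3": 0.050,
        }
    )  # 1/h per transported species class

    # regression study
    planted_slope: float = 0.47  # log-log density-ratio elasticity
    regression_noise_sd: float = 0.35  # sd of ln-ratio noise in city-table studies

    def __post_init__(self) -> None:
        if self.nrows < 2 or self.ncols < 2:
            raise ConfigurationError("grid must be at least 2x2")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.n_provinces < 1 or self.cities_per_province < 1:
            raise ConfigurationError("need at least one province and one city per province")
        if len(self.subsector_counts) != len(SECTORS):
            raise ConfigurationError("one subsector count per sector required")
        if any(c < 1 for c in self.subsector_counts):
            raise ConfigurationError("every sector needs at least one subsector")
        if set(self.species_totals) != set(SPECIES):
            raise ConfigurationError(f"species_totals must cover exactly {SPECIES}")
        if any(v < 0 for v in self.species_totals.values()):
            raise ConfigurationError("species totals must be nonnegative")
        if any(lam <= 0 for lam in self.loss_rates.values()):
            raise ConfigurationError("loss rates must be positive")
        if not 0 <= self.under5_fraction <= 1:
            raise ConfigurationError("under5_fraction must lie in [0, 1]")
        if self.z_cf < 0:
            raise ConfigurationError("z_cf must be nonnegative")


@dataclass
class ValuationConfig:
    """Monetization parameters, all in 2011 US$.

    ``vsl`` is the operative uniform value of statistical life in million US$
    per premature death; set to ``None`` to derive it from the OECD benchmark
    by benefit transfer (``vsl_oecd * (y_c / y_oecd) ** elasticity``).
    """

    vsl: float | None = 1.33  # million US$ per death; None -> benefit transfer
    vsl_oecd: float = 3.83  # million US$, OECD benchmark
    y_c: float = 1.0  # GDP per capita of the study country (2011 US$ PPP)
    y_oecd: float = 1.0  # reference OECD GDP per capita (2011 US$)
    income_elasticity: float = 1.2
    scc: float = 100.0  # US$ per tonne CO2
    vsl_low: float = 0.66  # million US$
    vsl_high: float = 4.36  # million US$
    scc_range: tuple[float, float] = (10.0, 1000.0)

    def __post_init__(self) -> None:
        for name in ("vsl_oecd", "y_c", "y_oecd", "scc", "vsl_low", "vsl_high"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.vsl is not None and self.vsl <= 0:
            raise ConfigurationError("vsl must be positive")
        if self.income_elasticity <= 0:
            raise ConfigurationError("income elasticity must be positive")
        lo, hi = self.scc_range
        if not 0 < lo <= hi:
            raise ConfigurationError("scc_range must satisfy 0 < min <= max")


@dataclass
class PipelineConfig:
    """Full pipeline configuration: scenario + valuation + run options."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    valuation: ValuationConfig = field(default_factory=ValuationConfig)
    stages: tuple[str, ...] = (
        "simulate",
        "forward",
        "forcing",
        "adjoint",
        "attribute",
        "monetize",
        "report",
    )
    output_dir: str = "runs/default"
    log_level: str = "INFO"


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_to_dict(config: PipelineConfig | ScenarioConfig | ValuationConfig) -> dict:
    return _to_plain(config)


def config_hash(config: PipelineConfig | ScenarioConfig | ValuationConfig) -> str:
    """Stable short hash of the canonical YAML form, used for provenance."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def _tupled(d: dict, key: str) -> None:
    if key in d and isinstance(d[key], list):
        d[key] = tuple(d[key])


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    scen = raw.get("scenario", {})
    _tupled(scen, "subsector_counts")
    val = raw.get("valuation", {})
    _tupled(val, "scc_range")
    return PipelineConfig(
        scenario=ScenarioConfig(**scen),
        valuation=ValuationConfig(**val),
        stages=tuple(raw.get("stages", PipelineConfig.stages)),
        output_dir=raw.get("output_dir", "runs/default"),
        log_level=raw.get("log_level", "INFO"),
    )
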