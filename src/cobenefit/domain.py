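"""Domain grid, region partition and subsector catalog types.

The model grid is abstract and equal-area: ``nrows x ncols`` square cells of
``cell_size`` km, 0-based row-major indices, no map projection and no
vertical dimension. Cells nest whole into cities, and cities nest whole into
provinces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SECTORS, ConfigurationError


@dataclass(frozen=True)
class DomainGrid:
    nrows: int
    ncols: int
    cell_size: float  # km
    mixing_height: float = 1.0  # km

    def __post_init__(self) -> None:
        if self.nrows < 2 or self.ncols < 2:
            raise ConfigurationError("grid must be at least 2x2")
        if self.cell_size <= 0 or self.mixing_height <= 0:
            raise ConfigurationError("cell_size and mixing_height must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def cell_area(self) -> float:
        """km^2 per cell."""
        return self.cell_size**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) cell-center coordinates in km, row-major broadcastable."""
        x = (np.arange(self.ncols) + 0.5) * self.cell_size
        y = (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(x, y)


@dataclass
class RegionPartition:
    """Per-cell province and city labels plus the city attribute table.

    ``province_of_cell`` and ``city_of_cell`` are integer rasters of the grid
    shape; every cell carries exactly one label per level and each city lies
    within a single province. ``city_attributes`` has one row per city with
    columns ``city_id, province_id, n_cells, population, population_density,
    solid_fuel_fraction``.
    """

    province_of_cell: np.ndarray
    city_of_cell: np.ndarray
    city_attributes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.province_of_cell.shape != self.city_of_cell.shape:
            raise ConfigurationError("province and city rasters must share the grid shape")
        # cities must nest within provinces
        df = pd.DataFrame(
            {"city": self.city_of_cell.ravel(), "prov": self.province_of_cell.ravel()}
        )
        if (df.groupby("city")["prov"].nunique() > 1).any():
            raise ConfigurationError("a city spans multiple provinces")

    @property
    def n_provinces(self) -> int:
        return int(self.province_of_cell.max()) + 1

    @property
    def n_cities(self) -> int:
        return int(self.city_of_cell.max()) + 1

    def labels(self, level: str) -> np.ndarray:
        if level == "province":
            return self.province_of_cell
        if level == "city":
            return self.city_of_cell
        raise KeyError(f"unknown region level {level!r}")


#: Named subsectors that anchor the otherwise generic catalog, keyed
#: (sector, name) -> (synergistic, domestic_solid_fuel).
_NAMED_SUBSECTORS: dict[str, list[tuple[str, bool, bool]]] = {
    "energy": [("bituminous_coal", True, False)],
    "industrial": [
        ("bituminous_coal", True, False),
        ("hydraulic_cement_production", True, False),
        ("iron_and_steel_production", True, False),
        ("dry_natural_gas", True, False),
        ("lime_production", True, False),
        ("coke_production", True, False),
        ("brick_production", True, False),
        ("non_combustion_process", False, False),
    ],
    "domestic": [
        ("bituminous_coal", True, True),
        ("anthracite_coal", True, True),
        ("brush_wood", True, True),
        ("crop_residue_burning", False, True),  # carbon-neutral biomass
        ("unorganized_waste", False, False),
    ],
    "transportation": [
        ("diesel_vehicles", True, False),
        ("gasoline_vehicles", True, False),
    ],
    "agricultural": [
        ("fertilizer_application", False, False),
        ("livestock_management", False, False),
        ("field_residue_burning", False, False),
    ],
}


@dataclass
class SubsectorCatalog:
    """Subsector metadata table.

    One row per subsector: ``subsector_id, sector, fuel_or_process,
    synergistic, domestic_solid_fuel``. Synergistic subsectors emit
    fuel-combustion CO2; non-synergistic ones (industrial non-combustion
    processes, agricultural activities, carbon-neutral biomass burning) have
    a CO2 slice that is identically zero.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subsector_id", "sector", "fuel_or_process", "synergistic", "domestic_solid_fuel"}
        if not required.issubset(self.table.columns):
            raise ConfigurationError(f"catalog table must have columns {sorted(required)}")
        if not set(self.table["sector"]).issubset(SECTORS):
            raise ConfigurationError("unknown sector name in catalog")

    @property
    def n_subsectors(self) -> int:
        return len(self.table)

    @property
    def subsector_ids(self) -> np.ndarray:
        return self.table["subsector_id"].to_numpy()

    def sector_of(self) -> pd.Series:
        return self.table.set_index("subsector_id")["sector"]

    def synergistic_mask(self) -> np.ndarray:
        return self.table["synergistic"].to_numpy(dtype=bool)


def build_catalog(subsector_counts: tuple[int, ...] = (6, 24, 15, 5, 3)) -> SubsectorCatalog:
    """Build the default subsector catalog with the given per-sector counts.

    Named subsectors come first within each sector; the remainder are generic
    ``fuel_##`` (synergistic) or ``process_##`` (non-synergistic) entries.
    Generic industrial/agricultural process slots are non-synergistic so the
    default 6/24/15/5/3 split yields 36 synergistic and 17 non-synergistic
    subsectors.
    """
    if len(subsector_counts) != len(SECTORS):
        raise ConfigurationError("one subsector count per sector required")
    # per-sector number of generic non-synergistic fillers under the default split
    generic_nonsyn = {"energy": 0, "industrial": 8, "domestic": 3, "transportation": 0, "agricultural": 99}
    rows = []
    sid = 0
    for sector, count in zip(SECTORS, subsector_counts):
        named = _NAMED_SUBSECTORS[sector][:count]
        n_generic = count - len(named)
        n_nonsyn = min(generic_nonsyn[sector], n_generic)
        entries = list(named)
        for k in range(n_generic):
            nonsyn = k < n_nonsyn
            name = f"{'process' if nonsyn else 'fuel'}_{k:02d}"
            entries.append((name, not nonsyn, False))
        for name, synergistic, dsf in entries:
            rows.append(
                {
                    "subsector_id": sid,
                    "sector": sector,
                    "fuel_or_process": name,
                    "synergistic": synergistic,
                    "domestic_solid_fuel": dsf,
                }
            )
            sid += 1
    return SubsectorCatalog(pd.DataFrame(rows))
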