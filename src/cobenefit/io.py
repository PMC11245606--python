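"""File formats: NetCDF grids, CSV tables, GeoJSON regions, provenance.

Gridded fields travel as NetCDF (classic format through xarray's scipy
backend) with named dimensions (species, month, subsector, row, col); region
partitions as GeoJSON polygons over the abstract cell coordinates plus a CSV
city-attribute table; configs as YAML. Every artifact written by a run
carries the run's config hash so mixed-provenance run directories can be
rejected. Conventions (cell-center coordinates, 0-based row-major indices,
months 1-12) are documented in FORMATS.md.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from shapely.geometry import Point, box, mapping, shape
from shapely.ops import unary_union

from .domain import DomainGrid, RegionPartition


def write_dataset(ds: xr.Dataset, path: str | Path, config_hash: str | None = None) -> None:
    ds = ds.copy()
    # scipy/NETCDF3 attrs must be scalars or strings
    ds.attrs = {k: (json.dumps(v) if isinstance(v, (list, dict)) else v)
                for k, v in ds.attrs.items()}
    if config_hash is not None:
        ds.attrs["config_hash"] = config_hash
    ds.to_netcdf(path, engine="scipy")


def read_dataset(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """CSV with an optional provenance header comment line."""
    path = Path(path)
    with path.open("w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def table_config_hash(path: str | Path) -> str | None:
    first = Path(path).read_text().splitlines()[0]
    if first.startswith("# config_hash="):
        return first.split("=", 1)[1]
    return None


def region_polygons(regions: RegionPartition, domain: DomainGrid, level: str) -> dict[int, object]:
    """Merged shapely polygon per region label, from unions of cell boxes."""
    labels = regions.labels(level)
    h = domain.cell_size
    out: dict[int, object] = {}
    for rid in np.unique(labels):
        cells = np.argwhere(labels == rid)
        boxes = [box(j * h, i * h, (j + 1) * h, (i + 1) * h) for i, j in cells]
        out[int(rid)] = unary_union(boxes)
    return out


def write_regions_geojson(regions: RegionPartition, domain: DomainGrid,
                          path: str | Path, level: str = "province") -> None:
    polys = region_polygons(regions, domain, level)
    features = [
        {
            "type": "Feature",
            "properties": {"region_id": rid, "level": level},
            "geometry": mapping(geom),
        }
        for rid, geom in polys.items()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_regions_geojson(path: str | Path) -> dict[int, object]:
    """region_id -> shapely geometry."""
    raw = json.loads(Path(path).read_text())
    if raw.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection with "
                         "features carrying a 'region_id' property")
    return {int(f["properties"]["region_id"]): shape(f["geometry"]) for f in raw["features"]}


def zonal_aggregate(field: np.ndarray, polygons: dict[int, object],
                    domain: DomainGrid) -> pd.Series:
    """Sum of a gridded field over each polygon, by cell-center membership.

    A cell belongs to the polygon covering its center; with the package's
    own region polygons this reproduces the label-raster aggregation
    exactly.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != domain.shape:
        raise ValueError(f"field shape {field.shape} != grid {domain.shape}")
    xg, yg = domain.cell_centers()
    sums = {}
    for rid, geom in polygons.items():
        total = 0.0
        for i in range(domain.nrows):
            for j in range(domain.ncols):
                if geom.covers(Point(xg[i, j], yg[i, j])):
                    total += field[i, j]
        sums[rid] = total
    return pd.Series(sums, name="zonal_sum").sort_index()


def zonal_ratio(health_field: np.ndarray, co2_field: np.ndarray,
                polygons: dict[int, object], domain: DomainGrid) -> pd.DataFrame:
    """Per-region contribution ratio from deposited gridded damage/CO2 fields."""
    h = zonal_aggregate(health_field, polygons, domain)
    c = zonal_aggregate(co2_field, polygons, domain)
    hs = 100.0 * h / h.sum() if h.sum() > 0 else h * 0.0
    cs = 100.0 * c / c.sum() if c.sum() > 0 else c * 0.0
    ratio = np.where(cs > 0, hs / cs.where(cs > 0, 1.0), np.nan)
    return pd.DataFrame(
        {"death_share_pct": hs, "co2_share_pct": cs, "ratio": ratio, "zero_co2": cs == 0}
    ).rename_axis("entity").reset_index()


def load_external_grids(manifest_path: str | Path) -> dict:
    """Load deposited cost/ratio grids and region polygons via a manifest.

    The YAML manifest maps the deposit's own variable names onto the
    pipeline's, since external schemas vary::

        grid: {nrows: 15, ncols: 15, cell_size: 36.0}
        fields:
          health_cost: {path: health.nc, variable: cost}
        regions: {path: provinces.geojson}

    Files are never downloaded; missing paths raise with the expected
    schema printed.
    """
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    gspec = manifest.get("grid")
    if not gspec:
        raise ValueError("manifest must declare grid: {nrows, ncols, cell_size}")
    domain = DomainGrid(int(gspec["nrows"]), int(gspec["ncols"]), float(gspec["cell_size"]),
                        float(gspec.get("mixing_height", 1.0)))
    out: dict = {"domain": domain, "fields": {}}
    for name, spec in manifest.get("fields", {}).items():
        fpath = base / spec["path"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"{fpath}: expected a NetCDF file with a (row, col) variable "
                f"{spec.get('variable', name)!r}"
            )
        ds = read_dataset(fpath)
        var = spec.get("variable", name)
        if var not in ds:
            raise KeyError(f"{fpath}: variable {var!r} not found; has {list(ds.data_vars)}")
        out["fields"][name] = ds[var].values
    if "regions" in manifest:
        rpath = base / manifest["regions"]["path"]
        if not rpath.exists():
            raise FileNotFoundError(f"{rpath}: expected a GeoJSON FeatureCollection "
                                    "with per-feature 'region_id' properties")
        out["regions"] = read_regions_geojson(rpath)
    return out
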