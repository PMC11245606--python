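# File and grid conventions

- **Grid**: abstract, equal-area, 2-D. `nrows x ncols` square cells of
  `cell_size` km. Indices are 0-based and row-major; cell `(i, j)` spans
  `[j*h, (j+1)*h] x [i*h, (i+1)*h]` in (x, y) km with `h = cell_size`, and
  its center is `((j+0.5)h, (i+0.5)h)`. No map projection, no vertical
  dimension.
- **Months**: integers 1–12. Annual exposure is the mean of the 12 monthly
  fields.
- **Species**: `OC, EC, PPM_other, SO2, NOx, NH3`, in that canonical order.
- **Gridded fields**: NetCDF (classic format, xarray scipy backend) with
  named dimensions drawn from `(species, month, subsector, row, col)`.
  Emissions are tonnes/month per cell; CO2 tonnes/month; PM2.5 µg/m³;
  sensitivities deaths per tonne-month.
- **Region partitions**: GeoJSON FeatureCollections of merged cell-box
  polygons over the abstract coordinates, one feature per region with
  `region_id` and `level` properties; the city attribute table is CSV
  (`city_id, province_id, n_cells, population, population_density,
  solid_fuel_fraction`).
- **Tables**: CSV. Share/ratio tables carry `entity, level, deaths, co2_t,
  death_share_pct, co2_share_pct, ratio, zero_co2`; cost tables add
  `health_cost_busd, climate_cost_busd, integrated_cost_busd, health_share`.
  IER parameters: `cause, alpha, beta, gamma, z_cf`; baseline mortality:
  `cause, rate`.
- **Config**: YAML; a snapshot is written beside each run's outputs.
- **Provenance**: every artifact written by a run carries the run config's
  16-hex-digit SHA-256 hash (NetCDF global attribute `config_hash`, CSV
  leading comment line `# config_hash=...`, `run_meta.json` in the run
  directory). A run directory created under a different hash is rejected.
- **Money**: 2011 US$. VSL in million US$ per death, SCC in US$ per tonne
  CO2, entity costs in billion US$.
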