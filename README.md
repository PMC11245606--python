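# cobenefit

Coordinated source attribution of PM2.5-related health damage and CO2
climate damage on gridded emission inventories.

Air-pollution control and decarbonization target largely the same
combustion sources, but the *source profiles* of the two damages differ:
health damage concentrates where emissions meet people, while CO2 follows
fuel burn alone. `cobenefit` quantifies that disparity. It attributes
premature mortality from ambient PM2.5 exposure to individual
sector/fuel/process emission subcategories through **adjoint
sensitivities** of a mortality cost function, monetizes health (value of
statistical life) and climate (social cost of carbon) damages into a single
integrated cost, and computes the comparative statistics that expose where
the two control agendas diverge — contribution ratios, dual rankings,
population-density elasticities and distributional curves.

Everything runs end to end on seeded synthetic data: a linear 2-D
advection–diffusion–loss transport surrogate with an exactly matched
discrete adjoint stands in for a full chemical-transport model, so the
whole chain is testable on a desktop in seconds.

## The model

The receptor-side cost function is nationwide annual premature mortality
attributable to long-term PM2.5 exposure,

```
J = Σ_{i,g} B_i · pop_g · (1 − 1/RR_i(z_g)),
RR_i(z) = 1 + α_i (1 − e^{−β_i x^{γ_i}}),   x = max(z − z_cf, 0),
```

the integrated exposure–response (IER) relative risk over five causes
(ischemic heart disease, stroke, COPD, lung cancer, and child ALRI), with
`B_i` baseline mortality rates, `pop_g` gridded population, `z_g`
annual-mean PM2.5 and `z_cf` the counterfactual concentration.

The gradient `F_g = ∂J/∂z_g` is the forcing propagated backward through the
transposed transport operator, yielding marginal sensitivities
`S_{p,g,m} = ∂J/∂E_{p,g,m}` (deaths per tonne of species *p* emitted in
grid *g*, month *m*). Attribution to subsector *s* is first-order
(marginal × total):

```
M_{g,m,s} = Σ_p  ∂J/∂E_{p,g,m} · ΔE_{p,g,m,s},
```

summed over OC, EC, other primary PM2.5, SO2, NOx and NH3. Monetization
applies a uniform VSL (default 1.33 million US$ per death, 2011 US$;
alternatively the OECD benchmark 3.83 M$ transferred by
`VSL_c = VSL_OECD (Y_c/Y_OECD)^e` with income elasticity `e = 1.2`) and an
SCC of 100 US$/t CO2; integrated cost = health + climate cost.

## Worked example

```python
from cobenefit import PipelineConfig, run_pipeline

cfg = PipelineConfig()
cfg.scenario.seed = 1
art = run_pipeline(cfg, output_dir="runs/demo")
print(art["costs"]["sector"][["entity", "death_share_pct", "co2_share_pct",
                              "integrated_cost_busd"]])
```

On the default synthetic scenario (40×40 grid of 36-km cells, 12 months,
53 subsectors split 6/24/15/5/3 across five sectors, 1.4 billion people)
this prints:

```
        entity  death_share_pct  co2_share_pct  integrated_cost_busd
  agricultural             7.91           0.00                 80.90
      domestic            32.41           2.78                361.85
        energy            18.30          56.79                811.71
    industrial            29.28          30.97                639.93
transportation            12.10           9.46                227.80
```

The disparity the package is built to measure is visible directly: the
domestic sector carries 32% of the attributed deaths on under 3% of the
CO2 (population-proximate, poorly controlled solid-fuel burning), while
energy generation carries 57% of the CO2 but 18% of the deaths. The run
directory additionally holds per-subsector, per-province, per-city and
per-grid share/ratio/cost tables, provincial dual rankings, the city-level
density–ratio regression and the summary JSON.

The same pipeline is scriptable from a shell:

```
cobenefit --seed 1 --out runs/demo report
```

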