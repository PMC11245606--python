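# Methods

## Scope and shape of the surrogate

The package reproduces the *analysis layer* of a coordinated
health/climate source-attribution study — cost function, adjoint
attribution, monetization, disparity statistics — while replacing the
full 3-D chemical-transport model and its adjoint with a desk-scale linear
surrogate. The surrogate is not a reduced-form fit of any particular model;
it is a self-consistent linear transport model chosen so that every
property the analysis relies on (exact discrete adjointness, linearity in
emissions, nonnegativity) holds by construction and can be tested to
machine precision.

## Transport surrogate

Steady-state advection–diffusion–loss per species class and month on an
abstract equal-area 2-D grid:

- **Discretization.** Finite volume; first-order upwind advection with face
  velocities averaged from adjacent cells; 5-point diffusion; first-order
  removal λ on the diagonal. Upwinding keeps the system matrix an M-matrix,
  so nonnegative emissions always produce nonnegative concentrations — a
  property we value above the numerical diffusion the scheme introduces.
- **Boundaries.** Outflow advective flux leaves the domain; inflow carries
  clean air; diffusive flux vanishes at edges. With λ > 0 the system is
  strictly diagonally dominant and nonsingular; λ = 0 is rejected at
  configuration time because no steady state exists.
- **Steady state per month** rather than time stepping: one sparse LU per
  (species class, month), 48 solves for the default scenario. The adjoint
  is the exact transpose solve of the same factorization, so the duality
  identity ⟨F, AE⟩ = ⟨AᵀF, E⟩ holds to round-off on any grid, and the
  full-chain gradient matches central finite differences of the forward +
  exposure-response pipeline to ~1e-8 relative error.
- **Units.** Emissions (tonnes/month) convert to a volume source (µg/m³/h)
  through the cell area, a fixed mixing height (default 1 km) and the mean
  month length (730.5 h); concentrations come out in µg/m³.
- **Chemistry** is linear fixed-yield: OC, EC and other primary PM2.5
  contribute their transported mass directly (yield 1); SO2, NOx and NH3
  are transported with their own loss rates and convert to secondary PM2.5
  mass with fixed yields (defaults 0.375, 0.13, 0.50 — the order of
  ammonium sulfate/nitrate stoichiometry times partial conversion). Real
  secondary-aerosol formation is nonlinear and coupled across precursors;
  the attribution formula is a first-order decomposition in either case,
  but the surrogate's attribution is exactly linear where a real model's is
  only locally so.
- **Annual-mean chain rule.** The burden depends on the annual mean of 12
  monthly fields, so each monthly sensitivity carries a uniform factor
  1/12.

## Exposure–response and its gradient

The IER form RR = 1 + α(1 − e^{−βx^γ}) with x = max(z − z_cf, 0) gives a
population-attributable fraction 1 − 1/RR ∈ [0, α/(1+α)). The analytic
concentration gradient uses RR′ = αβγ x^{γ−1} e^{−βx^γ}; for γ < 1 this
diverges as x → 0⁺, so the derivative is defined as 0 for x ≤ 1e-9 µg/m³ —
the forcing stays bounded and the bias is confined to cells sitting exactly
at the counterfactual. Default parameters are plausible rounded values in
the range of published IER fits (per-cause α 0.5–2.0, β 0.01–0.072,
γ 0.63–1.1, z_cf 5.8 µg/m³, baseline rates 0.2–1.7 per 1000 person-years);
they are configurable inputs of the scenario, not assertions about any
particular epidemiological fit. ALRI applies to a configurable under-five
population fraction (default 6%). Baseline rates are national by default
with a per-region override hook, since finer granularity is scenario-
specific.

## Attribution conventions

- ΔE in the attribution product is each subsector's **entire** emission:
  M is the subsector's marginal damage rate times its total amount, a
  first-order convention, not a zero-out re-simulation. Consequently the
  attributed national total Σ M understates the total burden J wherever the
  IER has saturated; the two converge as emissions are scaled down, with
  the gap vanishing quadratically when the dose-response is smooth (γ = 1,
  z_cf = 0). The acceptance checks verify exactly that: halving the
  emission scale quarters |ΣM − J|.
- Shares are percentages of the national total over an exhaustive
  partition (sector, subsector, grid, city, province) and sum to 100 by
  construction; the contribution ratio is death-share over CO2-share, with
  zero-CO2 entities flagged rather than dropped. The CO2-share-weighted
  mean ratio equals the death share carried by CO2-emitting entities; it is
  identically 1 at all spatial levels and falls below 1 at subsector level
  by exactly the non-synergistic subsectors' death share.
- Emission-weighted monthly averaging of daily sensitivities is provided
  for daily inputs; an all-zero-emission month falls back to the unweighted
  mean and logs the fact.
- Cells belong whole to one city and one province (the abstract grid nests
  cleanly); annual sums are formed before ratios.

## Monetization

Uniform VSL across all entities (an explicit ethics convention), default
1.33 million 2011 US$ per death, with the OECD-benchmark benefit transfer
VSL_OECD (Y_c/Y_OECD)^e available when GDP inputs are supplied (those are
config values, not constants of the package). SCC default 100 US$/t
(global value at a 2.5% discount rate, taken as an input). Uncertainty
sweep: VSL ∈ {0.66, central, 4.36} M$ × SCC ∈ [10, 1000] $/t; SCC shifts
only climate cost, so health-cost rankings are invariant along that axis —
asserted as a structural test, not an observation.

## Synthetic-data generator

The generator emulates the *structure* of the study inputs, not China:

- **Domain** 40×40 cells of 36 km (desk-scale; full pipeline < 5 s),
  nested Voronoi province/city partition (6 provinces × 3 cities default).
- **Population** 1.4 billion: lognormal rural background (σ = 0.8) plus
  Gaussian city plumes with 100× core-over-background contrast, rescaled
  to the national total.
- **Inventory** 53 subsectors (6/24/15/5/3 across energy, industrial,
  domestic, transportation, agricultural; 36 synergistic, 17
  non-synergistic). Within-sector apportionment is Dirichlet (partition of
  unity per sector). Species profiles are Dirichlet draws biased toward
  OC/EC/PPM for domestic solid-fuel subsectors and toward NH3 for
  agriculture; national annual totals are rescaled to fixed per-species
  targets (order 1e6–2e7 t/yr). Domestic subsectors get winter-peaked
  seasonality (amplitude 0.6); others a random-phase 0.25. CO2 (11 Gt
  total) couples only to synergistic subsectors with an energy/industry-
  heavy split; non-synergistic CO2 is identically zero.
- **Meteorology** monthly rotating wind (mean 10 km/h, CFL-checked against
  the cell size), diffusivity 50 km²/h, per-class loss rates 0.008–0.05 /h
  (particle lifetimes of days, shorter-lived gases).
- **Determinism.** Every op draws from its own RNG stream derived from the
  master seed by a fixed offset, so artifacts are bit-reproducible and new
  ops cannot perturb existing draws.

What the generator does **not** emulate: real terrain and stagnation
(Sichuan-basin-type accumulation), vertical structure, nonlinear chemistry,
realistic inter-provincial contrast in fuel quality, or the true spatial
skewness of population and emissions. Passing tests therefore demonstrate
the correctness and internal consistency of the analysis machinery, not the
magnitudes of any real-world attribution. The synthetic annual-mean PM2.5
is high (~100–400 µg/m³) because continental-scale emission totals are
placed on a domain a fraction of the real area; this saturates the IER
harder than reality and makes the first-order attribution gap larger, which
the tests account for explicitly.

The city-level density–ratio elasticity study plants its slope (0.47, with
a 0.35-sd log-normal noise) directly in a generated city table: exact
planting *through* the transport operator is not controllable, because
transport smears source–receptor relationships. The end-to-end pipeline
city table is checked for a positive, well-formed elasticity; exact
recovery (noiseless slope, R² = 1) and 95%-CI coverage (~95% over 500
replicates, calibrated against 5000) are established at the table level
where the ground truth is known.

## Numerical choices

- Sparse LU (SuperLU) per operator; transpose solves reuse the
  factorization.
- Gradient probes perturb by 1e-3 of the species' national monthly scale
  per cell; probes that would drive emissions negative are skipped and
  flagged.
- Ranking ties break by entity identifier (documented, deterministic).
- QQ curves order cells by population descending with index tie-breaks;
  zero total cost yields a flat curve rather than an error; zero total
  population is an error (the axis is undefined).
- Land shares are cell-count fractions — exact on the equal-area grid; a
  projected grid would need area weighting.
- Regression strata split at a solid-fuel fraction of 1%; nonpositive
  densities/ratios are dropped with a logged warning; strata under 3 cities
  are fitted but flagged.

## Known limitations

- The transport surrogate is first-order accurate and strongly diffusive;
  it is a correctness vehicle, not a dispersion model.
- Linear chemistry ignores precursor coupling (e.g., NH3-limited nitrate
  formation), which in real atmospheres redistributes attribution across
  precursors.
- The external-data validation path (deposited gridded fields + boundary
  polygons) is exercised against synthetic deposits written by the package
  itself; validating against a real deposit requires the user to supply
  files and a schema manifest locally.
- No indoor exposure, no years-of-life-lost, no age structure beyond the
  under-five ALRI slice, no economic input–output assignment.
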