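"""PM2.5-attributable mortality: the cost function J and its gradient.

The receptor-side cost function is the nationwide annual premature death
count attributable to long-term ambient PM2.5 exposure,

    J = sum_{i,g} B_i * pop_g * (1 - 1 / RR_i(z_g)),

with the integrated exposure-response (IER) relative risk

    RR_i(z) = 1 + alpha_i * (1 - exp(-beta_i * x**gamma_i)),
    x = max(z - z_cf, 0),

so the population-attributable fraction 1 - 1/RR lies in
[0, alpha/(1+alpha)). The gradient of J with respect to the concentration
field, F_g = dJ/dz_g, is the forcing injected into the adjoint transport
solve.

Five causes are carried: ischemic heart disease, stroke, chronic
obstructive pulmonary disease and lung cancer for adults, and acute lower
respiratory infections for children under five (the ALRI baseline rate is
applied to a configurable under-five population fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CAUSES, ConfigurationError

#: below this excess exposure (ug/m3) the risk derivative is defined as 0,
#: bounding the forcing at the z_cf kink and the gamma < 1 singularity
KINK_EPS = 1e-9


@dataclass
class IERParameters:
    """Per-cause IER curve parameters and the shared counterfactual.

    ``alpha`` is the asymptotic excess risk (dimensionless), ``beta`` the
    rate per (ug/m3)**gamma, ``gamma`` the exposure exponent and ``z_cf``
    the counterfactual concentration in ug/m3 below which no excess risk is
    assigned. ``allow_zero_alpha`` is a test hook: alpha = 0 yields RR = 1
    identically.
    """

    causes: tuple[str, ...] = CAUSES
    alpha: np.ndarray = field(default_factory=lambda: np.array([0.89, 1.10, 0.50, 0.60, 2.00]))
    beta: np.ndarray = field(default_factory=lambda: np.array([0.072, 0.025, 0.035, 0.025, 0.010]))
    gamma: np.ndarray = field(default_factory=lambda: np.array([0.63, 0.85, 0.70, 0.76, 1.10]))
    z_cf: float = 5.8
    allow_zero_alpha: bool = False

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        n = len(self.causes)
        if not (self.alpha.shape == self.beta.shape == self.gamma.shape == (n,)):
            raise ConfigurationError("alpha, beta, gamma must each have one value per cause")
        lo = 0.0 if self.allow_zero_alpha else None
        if (self.alpha < 0).any() or (lo is None and (self.alpha == 0).any()):
            raise ConfigurationError("alpha must be positive (zero only with allow_zero_alpha)")
        if (self.beta <= 0).any() or (self.gamma <= 0).any():
            raise ConfigurationError("beta and gamma must be positive")
        if self.z_cf < 0:
            raise ConfigurationError("z_cf must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cause": self.causes,
                "alpha": self.alpha,
                "beta": self.beta,
                "gamma": self.gamma,
                "z_cf": self.z_cf,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, allow_zero_alpha: bool = False) -> "IERParameters":
        z_cf = float(df["z_cf"].iloc[0])
        if not np.allclose(df["z_cf"], z_cf):
            raise ConfigurationError("z_cf must be shared across causes")
        return cls(
            causes=tuple(df["cause"]),
            alpha=df["alpha"].to_numpy(dtype=float),
            beta=df["beta"].to_numpy(dtype=float),
            gamma=df["gamma"].to_numpy(dtype=float),
            z_cf=z_cf,
            allow_zero_alpha=allow_zero_alpha,
        )


@dataclass
class BaselineMortality:
    """Cause-specific baseline mortality rates, deaths per person-year.

    ``rates`` maps cause -> national rate; an optional per-region override is
    supported through ``regional_rates`` (region label -> cause -> rate) but
    the default granularity is national.
    """

    rates: dict[str, float] = field(
        default_factory=lambda: {
            "IHD": 1.7e-3,
            "stroke": 1.6e-3,
            "COPD": 0.9e-3,
            "lung_cancer": 0.6e-3,
            "ALRI": 0.2e-3,
        }
    )
    under5_fraction: float = 0.06

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rates.values()):
            raise ConfigurationError("baseline mortality rates must be nonnegative")
        if not 0 <= self.under5_fraction <= 1:
            raise ConfigurationError("under5_fraction must lie in [0, 1]")

    def rate_vector(self, causes: tuple[str, ...]) -> np.ndarray:
        try:
            return np.array([self.rates[c] for c in causes], dtype=float)
        except KeyError as exc:
            raise ConfigurationError(f"missing baseline rate for cause {exc}") from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cause": list(self.rates), "rate": list(self.rates.values())})


@dataclass
class HealthBurden:
    """J and its per-grid / per-cause decomposition."""

    total: float  # J, deaths/year
    per_grid: np.ndarray  # J_g
    per_grid_cause: np.ndarray  # J_{g,i}, shape (n_causes, nrows, ncols)
    causes: tuple[str, ...]

    def per_cause(self) -> pd.Series:
        return pd.Series(
            self.per_grid_cause.sum(axis=(1, 2)), index=list(self.causes), name="deaths"
        )


def excess_exposure(z: np.ndarray | float, z_cf: float) -> np.ndarray | float:
    """Exposure above the counterfactual: max(z - z_cf, 0)."""
    z = np.asarray(z, dtype=float)
    if (z < 0).any() or z_cf < 0:
        raise ValueError("concentrations and z_cf must be nonnegative")
    out = np.maximum(z - z_cf, 0.0)
    return out if out.ndim else float(out)


def relative_risk(z: np.ndarray | float, alpha: float, beta: float, gamma: float,
                  z_cf: float) -> np.ndarray | float:
    """IER relative risk RR(z) = 1 + alpha (1 - exp(-beta x**gamma)).

    Monotone nondecreasing in z, equal to 1 at and below z_cf, saturating at
    1 + alpha.
    """
    if alpha < 0 or beta <= 0 or gamma <= 0:
        raise ValueError("require alpha >= 0, beta > 0, gamma > 0")
    x = np.asarray(excess_exposure(z, z_cf), dtype=float)
    rr = 1.0 + alpha * (1.0 - np.exp(-beta * np.power(x, gamma)))
    return rr if rr.ndim else float(rr)


def relative_risk_derivative(z: np.ndarray | float, alpha: float, beta: float,
                             gamma: float, z_cf: float) -> np.ndarray | float:
    """dRR/dz = alpha beta gamma x**(gamma-1) exp(-beta x**gamma) for x > 0.

    Defined as 0 for x <= KINK_EPS, which bounds the derivative where
    gamma < 1 would make it diverge at the counterfactual kink.
    """
    x = np.asarray(excess_exposure(z, z_cf), dtype=float)
    safe = np.where(x > KINK_EPS, x, 1.0)
    d = alpha * beta * gamma * safe ** (gamma - 1.0) * np.exp(-beta * safe**gamma)
    out = np.where(x > KINK_EPS, d, 0.0)
    return out if out.ndim else float(out)


def _effective_population(pop: np.ndarray, causes: tuple[str, ...],
                          under5_fraction: float) -> np.ndarray:
    """Per-cause exposed population: the under-five slice for ALRI."""
    pop = np.asarray(pop, dtype=float)
    frac = np.array([under5_fraction if c == "ALRI" else 1.0 for c in causes])
    return frac[:, None, None] * pop[None, :, :]


def attributable_mortality(z_annual: np.ndarray, pop: np.ndarray,
                           baseline: BaselineMortality,
                           params: IERParameters) -> HealthBurden:
    """Evaluate J and its decomposition on an annual-mean exposure field.

    J_{g,i} = B_i * pop_g * (1 - 1/RR_i(z_g)); deaths are additive over
    grids and causes.
    """
    z_annual = np.asarray(z_annual, dtype=float)
    pop = np.asarray(pop, dtype=float)
    if z_annual.shape != pop.shape:
        raise ValueError(f"exposure {z_annual.shape} and population {pop.shape} shapes differ")
    if (pop < 0).any():
        raise ValueError("population must be nonnegative")
    B = baseline.rate_vector(params.causes)
    pop_eff = _effective_population(pop, params.causes, baseline.under5_fraction)
    per_gc = np.empty((len(params.causes),) + z_annual.shape)
    for i in range(len(params.causes)):
        rr = relative_risk(z_annual, params.alpha[i], params.beta[i], params.gamma[i], params.z_cf)
        per_gc[i] = B[i] * pop_eff[i] * (1.0 - 1.0 / rr)
    return HealthBurden(
        total=float(per_gc.sum()),
        per_grid=per_gc.sum(axis=0),
        per_grid_cause=per_gc,
        causes=params.causes,
    )


def mortality_gradient(z_annual: np.ndarray, pop: np.ndarray,
                       baseline: BaselineMortality,
                       params: IERParameters) -> np.ndarray:
    """Adjoint forcing F_g = dJ/dz_g = pop_g sum_i B_i RR_i'(z_g)/RR_i(z_g)^2.

    Nonnegative; zero wherever population is zero or z_g <= z_cf.
    """
    z_annual = np.asarray(z_annual, dtype=float)
    pop = np.asarray(pop, dtype=float)
    if z_annual.shape != pop.shape:
        raise ValueError(f"exposure {z_annual.shape} and population {pop.shape} shapes differ")
    B = baseline.rate_vector(params.causes)
    pop_eff = _effective_population(pop, params.causes, baseline.under5_fraction)
    F = np.zeros_like(z_annual)
    for i in range(len(params.causes)):
        rr = relative_risk(z_annual, params.alpha[i], params.beta[i], params.gamma[i], params.z_cf)
        drr = relative_risk_derivative(
            z_annual, params.alpha[i], params.beta[i], params.gamma[i], params.z_cf
        )
        F += B[i] * pop_eff[i] * drr / rr**2
    return F
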