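"""Forward Monte-Carlo propagation of parameter uncertainty.

Each uncertain scalar of the biomass → capacity → stocking chain carries a
distribution: truncated normals for the conversion factors (all mass inside
the stated bounds) and uniforms, given as (mean, sd), for the relative
errors of the NPP product and the aboveground-fraction model.  A draw
samples one value per parameter and applies it globally — the uncertain
quantities are global constants, so perturbing them per pixel would
understate map-level uncertainty — then reruns the deterministic chain.
The ensemble is summarised per pixel by its median and its coefficient of
variation (CV = 100·sd/mean, sample sd), mirroring how interannual
variability is measured.

Default parameter set
---------------------
==================  =================  ===========  =====  ========
parameter           distribution       bounds       mean   sd
==================  =================  ===========  =====  ========
intake              truncated normal   0.018–0.04   0.02   0.001
carbon              truncated normal   0.47–0.50    mid    range/4
cattle AU factor    truncated normal   0.50–1.25    1.00   0.125
buffalo AU factor   truncated normal   0.60–0.70    mid    range/4
sheep AU factor     truncated normal   0.10–0.15    mid    range/4
goat AU factor      truncated normal   0.10–0.15    mid    range/4
horse AU factor     truncated normal   0.40–1.80    mid    range/4
npp_factor          uniform            mean±√3·sd   1      0.07
fanpp_factor        uniform            mean±√3·sd   1      0.14058
==================  =================  ===========  =====  ========

Rows that state bounds only take mean = midpoint and sd = range/4 (≈95 % of
the untruncated mass inside the bounds).  Rows that also state a mean take
sd = (distance to the nearer bound)/2 — for cattle that is 0.125, putting
the upper bound two sd above the stated mean of 1.00, and for intake 0.001,
keeping the sampled mean close to the stated 0.02 despite the strongly
asymmetric bounds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .agb import AGBParams, compute_agb
from .grids import AnnualStack, Grid, nanmedian
from .stocking import (
    DEFAULT_AU_FACTORS,
    AnimalUnitParams,
    animal_units,
    carrying_capacity,
    median_rsd_window,
)

SQRT3 = float(np.sqrt(3.0))


@dataclass(frozen=True)
class ParamSpec:
    """Distribution of one uncertain scalar parameter."""

    name: str
    kind: str  # "truncated_normal" | "uniform"
    lower: float
    upper: float
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"truncated_normal", "uniform"}:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.lower >= self.upper:
            raise ValueError(f"{self.name}: lower must be below upper")
        m, s = self.effective_mean, self.effective_sd
        if not self.lower <= m <= self.upper:
            raise ValueError(f"{self.name}: mean {m} outside bounds")
        if s <= 0:
            raise ValueError(f"{self.name}: sd must be positive")

    @classmethod
    def truncated_normal(cls, name, lower, upper, mean=None, sd=None) -> "ParamSpec":
        return cls(name, "truncated_normal", float(lower), float(upper),
                   None if mean is None else float(mean),
                   None if sd is None else float(sd))

    @classmethod
    def uniform_mean_sd(cls, name, mean, sd) -> "ParamSpec":
        """Uniform specified by (mean, sd): support is mean ± √3·sd."""
        mean, sd = float(mean), float(sd)
        half = SQRT3 * sd
        return cls(name, "uniform", mean - half, mean + half, mean, sd)

    @classmethod
    def degenerate(cls, name, value) -> "ParamSpec":
        """Zero-width stand-in: every draw equals ``value``."""
        eps = max(abs(value), 1.0) * 1e-15
        return cls(name, "uniform", value - eps, value + eps, value, eps / SQRT3)

    @property
    def effective_mean(self) -> float:
        return 0.5 * (self.lower + self.upper) if self.mean is None else self.mean

    @property
    def effective_sd(self) -> float:
        if self.sd is not None:
            return self.sd
        if self.mean is None:
            # bounds-only row: midpoint mean, ≈95 % of untruncated mass inside
            return (self.upper - self.lower) / 4.0
        # stated mean: keep the nearer bound two sd away, so the truncation
        # stays mild and the distribution's mean stays near the stated one
        return min(self.mean - self.lower, self.upper - self.mean) / 2.0


def default_specs() -> dict[str, ParamSpec]:
    """The default uncertain-parameter set (see module docstring)."""
    return {
        "intake": ParamSpec.truncated_normal("intake", 0.018, 0.04, mean=0.02),
        "carbon": ParamSpec.truncated_normal("carbon", 0.47, 0.50),
        "cattle": ParamSpec.truncated_normal("cattle", 0.50, 1.25, mean=1.00, sd=0.125),
        "buffalo": ParamSpec.truncated_normal("buffalo", 0.60, 0.70),
        "sheep": ParamSpec.truncated_normal("sheep", 0.10, 0.15),
        "goat": ParamSpec.truncated_normal("goat", 0.10, 0.15),
        "horse": ParamSpec.truncated_normal("horse", 0.40, 1.80),
        "npp_factor": ParamSpec.uniform_mean_sd("npp_factor", 1.0, 0.07),
        "fanpp_factor": ParamSpec.uniform_mean_sd("fanpp_factor", 1.0, 0.198 * 0.71),
    }


def _param_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, parameter name)."""
    tag = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def sample_parameter(spec: ParamSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` values from the parameter's distribution.

    All draws lie inside [lower, upper]; the stream is keyed by the seed and
    the parameter name, so parameters sample independently.
    """
    if n < 1:
        raise ValueError("need at least one draw")
    rng = _param_rng(seed, spec.name)
    if spec.kind == "uniform":
        return rng.uniform(spec.lower, spec.upper, size=n)
    mean, sd = spec.effective_mean, spec.effective_sd
    a = (spec.lower - mean) / sd
    b = (spec.upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_all(specs: Mapping[str, ParamSpec], n: int, seed: int) -> dict[str, np.ndarray]:
    return {key: sample_parameter(spec, n, seed) for key, spec in specs.items()}


@dataclass
class EnsembleSummary:
    """Per-pixel median and CV (%) over Monte-Carlo draws."""

    median: Grid
    cv: Grid
    n_draws: int


def ensemble_cv(draws: np.ndarray, template: Grid) -> Grid:
    """CV (%) per pixel over the draw axis (axis 0); nodata where mean = 0."""
    if draws.shape[0] < 2:
        raise ValueError("CV needs at least two draws")
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = draws.mean(axis=0)
        sd = draws.std(axis=0, ddof=1)
        cv = 100.0 * sd / mean
    cv[mean == 0] = np.nan
    return template.like(cv)


def _summarize(draws: np.ndarray, template: Grid, n: int) -> EnsembleSummary:
    med = template.like(np.median(draws, axis=0))
    if n >= 2:
        cv = ensemble_cv(draws, template)
    else:
        cv = template.like(np.zeros(template.shape))
    return EnsembleSummary(median=med, cv=cv, n_draws=n)


def propagate(
    npp_stack: AnnualStack,
    mat_grid: Grid,
    canopy_grid: Grid,
    slope_grid: Grid,
    headcounts: Mapping[str, Grid],
    specs: Mapping[str, ParamSpec] | None = None,
    *,
    n: int = 1000,
    seed: int = 0,
    window_years: Sequence[int] | None = None,
    agb_params: AGBParams | None = None,
) -> dict[str, EnsembleSummary]:
    """Propagate parameter uncertainty through AGB → CC → RSD.

    Per draw: the NPP stack is scaled by the sampled NPP factor, the
    aboveground fraction by the sampled f_ANPP factor, carbon conversion
    and intake take their sampled values, and headcounts convert with the
    sampled species factors.  AGB and CC are aggregated as the per-pixel
    median over ``window_years`` (defaults to all years); RSD divides the
    sampled animal units by the sampled CC year-by-year and takes the
    window median.  Returns ``{"agb", "cc", "rsd"}`` ensemble summaries.
    """
    if n < 1:
        raise ValueError("need n >= 1 draws")
    specs = default_specs() if specs is None else dict(specs)
    agb_params = agb_params or AGBParams()
    window = list(window_years) if window_years is not None else list(npp_stack.years)
    sub = npp_stack.select(window)
    template = sub.geometry
    draws = sample_all(specs, n, seed)
    sampled_species = [s for s in headcounts if s in specs]

    agb_draws = np.empty((n, *template.shape))
    cc_draws = np.empty((n, *template.shape))
    rsd_draws = np.empty((n, *template.shape))
    for d in range(n):
        params_d = replace(agb_params, carbon_factor=float(draws["carbon"][d]))
        fanpp_f = float(draws["fanpp_factor"][d])
        npp_f = float(draws["npp_factor"][d])
        au_params = AnimalUnitParams(daily_intake_fraction=float(draws["intake"][d]))
        factors = dict(DEFAULT_AU_FACTORS)
        factors.update({s: float(draws[s][d]) for s in sampled_species})
        au_grid = animal_units(headcounts, factors)

        cc_layers = []
        agb_layers = []
        for year in window:
            npp_y = sub[year]
            npp_scaled = npp_y.like(npp_y.masked() * npp_f)
            agb = compute_agb(npp_scaled, mat_grid, canopy_grid, slope_grid, params_d)
            # the f_ANPP factor is a multiplicative error on the aboveground
            # fraction, hence on AGB directly
            agb = agb.like(agb.masked() * fanpp_f)
            agb_layers.append(agb)
            cc_layers.append(carrying_capacity(agb, au_params))
        agb_stack_d = AnnualStack(years=window, layers=agb_layers)
        cc_stack_d = AnnualStack(years=window, layers=cc_layers)
        agb_draws[d] = nanmedian(agb_stack_d.to_array(), axis=0)
        cc_draws[d] = nanmedian(cc_stack_d.to_array(), axis=0)
        rsd_draws[d] = median_rsd_window(au_grid, cc_stack_d, window).masked()

    return {
        "agb": _summarize(agb_draws, template, n),
        "cc": _summarize(cc_draws, template, n),
        "rsd": _summarize(rsd_draws, template, n),
    }
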