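"""Carrying capacity, animal units, and relative stocking density.

Carrying capacity (CC) converts the annual aboveground biomass supply into
the number of reference grazers it can feed:

    CC = AGB_kg_km2 / (weight_AU · intake_daily · 365)   [AU km⁻² yr⁻¹]

where one animal unit (AU) is a 455 kg grazer eating a daily dry-matter
fraction of its body weight (point value 0.02, plausible range
0.018–0.04).  Reported species headcounts are converted to AU densities
with species conversion factors, and the relative stocking density

    RSD = AU / CC

measures grazing pressure.  RSD is classified against the minimum (0.20)
and maximum (0.65) proper-use factors from the rangeland literature:
below 0.20 is low pressure, 0.20–0.65 medium, above 0.65 overstocked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grids import AnnualStack, Grid, nanmedian, nanmin

AU_WEIGHT_KG = 455.0
DAILY_INTAKE = 0.02
DAYS_PER_YEAR = 365.0
G_M2_TO_KG_KM2 = 1000.0  # 1 g m⁻² = 10⁶ g km⁻² = 10³ kg km⁻²

#: Point-estimate animal-unit conversion factors (interval midpoints, or the
#: stated mean for cattle), keyed by species.
DEFAULT_AU_FACTORS: dict[str, float] = {
    "cattle": 1.00,
    "buffalo": 0.65,
    "sheep": 0.125,
    "goat": 0.125,
    "horse": 1.10,
}

CLASS_NODATA = -1
CLASS_LOW = 0
CLASS_MEDIUM = 1
CLASS_OVERSTOCKED = 2
CLASS_LABELS = {
    CLASS_LOW: "low pressure",
    CLASS_MEDIUM: "medium pressure",
    CLASS_OVERSTOCKED: "overstocked",
}


@dataclass
class AnimalUnitParams:
    au_weight: float = AU_WEIGHT_KG
    daily_intake_fraction: float = DAILY_INTAKE

    def __post_init__(self) -> None:
        if self.au_weight <= 0:
            raise ValueError("AU weight must be positive")
        if self.daily_intake_fraction <= 0:
            raise ValueError("daily intake fraction must be positive")


@dataclass
class RSDClassScheme:
    """Stocking-pressure class boundaries from proper-use factors.

    The printed interval 0.20–0.65 is read as closed, so both boundary
    values classify as medium pressure.
    """

    low_max: float = 0.20
    med_max: float = 0.65
    labels: Mapping[int, str] = field(default_factory=lambda: dict(CLASS_LABELS))

    def __post_init__(self) -> None:
        if not 0 < self.low_max < self.med_max:
            raise ValueError("need 0 < low_max < med_max")


def carrying_capacity(agb_grid: Grid, params: AnimalUnitParams | None = None) -> Grid:
    """Carrying capacity (AU km⁻² yr⁻¹) from AGB (g m⁻² yr⁻¹)."""
    params = params or AnimalUnitParams()
    agb_kg_km2 = agb_grid.masked() * G_M2_TO_KG_KM2
    annual_requirement = params.au_weight * params.daily_intake_fraction * DAYS_PER_YEAR
    return agb_grid.like(agb_kg_km2 / annual_requirement)


def animal_units(
    headcount_grids: Mapping[str, Grid],
    factors: Mapping[str, float] | None = None,
) -> Grid:
    """Total animal-unit density (AU km⁻²) from species headcounts (head km⁻²).

    ``factors`` maps species to AU-per-head conversion factors; a headcount
    species absent from it is an error.
    """
    factors = DEFAULT_AU_FACTORS if factors is None else factors
    if not headcount_grids:
        raise ValueError("no headcount layers given")
    grids = list(headcount_grids.values())
    ref = grids[0]
    for g in grids[1:]:
        if not g.same_geometry(ref):
            raise ValueError("headcount layers must share geometry")
    total = np.zeros(ref.shape)
    any_valid = np.zeros(ref.shape, dtype=bool)
    for species, grid in headcount_grids.items():
        if species not in factors:
            raise KeyError(f"no AU conversion factor for species {species!r}")
        vals = grid.masked()
        valid = np.isfinite(vals)
        total[valid] += factors[species] * vals[valid]
        any_valid |= valid
    total[~any_valid] = np.nan
    return ref.like(total)


def rsd(au_grid: Grid, cc_grid: Grid) -> Grid:
    """Relative stocking density AU/CC.

    Zero capacity with stock present yields +inf (any stock on zero forage
    exceeds capacity, so the cell classifies as overstocked); zero capacity
    with zero stock is nodata.
    """
    if not au_grid.same_geometry(cc_grid):
        raise ValueError("AU and CC grids must share geometry")
    au = au_grid.masked()
    cc = cc_grid.masked()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = au / cc
    zero_cc = cc == 0
    ratio[zero_cc & (au > 0)] = np.inf
    ratio[zero_cc & (au == 0)] = np.nan
    return au_grid.like(ratio)


def classify_rsd(rsd_grid: Grid, scheme: RSDClassScheme | None = None) -> Grid:
    """Three-class stocking-pressure labels (0 low / 1 medium / 2 overstocked)."""
    scheme = scheme or RSDClassScheme()
    r = rsd_grid.masked()
    out = np.full(r.shape, CLASS_NODATA, dtype=np.int64)
    defined = np.isfinite(r) | np.isposinf(r)
    out[defined & (r < scheme.low_max)] = CLASS_LOW
    out[defined & (r >= scheme.low_max) & (r <= scheme.med_max)] = CLASS_MEDIUM
    out[defined & (r > scheme.med_max)] = CLASS_OVERSTOCKED
    return Grid(out, rsd_grid.transform, rsd_grid.crs, nodata=CLASS_NODATA)


def _annual_ratios(au_grid: Grid, cc_stack: AnnualStack) -> np.ndarray:
    if not au_grid.same_geometry(cc_stack.geometry):
        raise ValueError("AU grid and CC stack must share geometry")
    au = au_grid.masked()
    ratios = []
    for _, cc_grid in cc_stack:
        cc = cc_grid.masked()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = au / cc
        zero_cc = cc == 0
        ratio[zero_cc & (au > 0)] = np.inf
        ratio[zero_cc & (au == 0)] = np.nan
        ratios.append(ratio)
    return np.stack(ratios)


def median_rsd_window(
    au_grid: Grid, cc_stack: AnnualStack, window_years: Sequence[int]
) -> Grid:
    """Per-pixel median of annual AU/CC ratios over a window of years.

    The headline stocking-density map uses the 2010 livestock census against
    the median of the five annual ratios 2008–2012, damping single-year
    forage anomalies.
    """
    window_years = list(window_years)
    if not window_years:
        raise ValueError("empty window")
    sub = cc_stack.select(window_years)
    ratios = _annual_ratios(au_grid, sub)
    med = nanmedian(ratios, axis=0)
    return au_grid.like(med)


def rsd_min_cc(au_grid: Grid, cc_stack: AnnualStack) -> Grid:
    """RSD against the per-pixel minimum CC over all years.

    Answers how much stock each location could sustain in its worst forage
    year; always at least as large as the median-window RSD.
    """
    if len(cc_stack) == 0:
        raise ValueError("empty CC stack")
    cc_arr = cc_stack.to_array()
    cc_min = nanmin(cc_arr, axis=0)
    min_grid = cc_stack.geometry.like(cc_min)
    return rsd(au_grid, min_grid)


def overstocked_year_fraction(
    au_grid: Grid, cc_stack: AnnualStack, scheme: RSDClassScheme | None = None
) -> Grid:
    """Per-pixel fraction of years whose annual RSD exceeds the overstocking bound."""
    scheme = scheme or RSDClassScheme()
    if len(cc_stack) == 0:
        raise ValueError("empty CC stack")
    ratios = _annual_ratios(au_grid, cc_stack)
    defined = np.isfinite(ratios) | np.isposinf(ratios)
    over = defined & (ratios > scheme.med_max)
    n_defined = defined.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = over.sum(axis=0) / n_defined
    frac[n_defined == 0] = np.nan
    return au_grid.like(frac)


def mask_livestock_grazing(data, system_mask: Grid):
    """Restrict a grid or stack to the livestock-grazing production system.

    Cells outside the boolean mask become nodata; values inside pass through
    unchanged.
    """
    keep = system_mask.values.astype(bool)

    def _mask_one(grid: Grid) -> Grid:
        if grid.shape != system_mask.shape or not np.allclose(
            grid.transform, system_mask.transform
        ):
            raise ValueError("mask and data geometry mismatch")
        vals = grid.masked()
        vals[~keep] = np.nan
        if grid.is_float:
            return grid.like(vals)
        out = grid.values.copy()
        out[~keep] = grid.nodata
        return grid.like(out)

    if isinstance(data, AnnualStack):
        return data.map(_mask_one)
    return _mask_one(data)
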