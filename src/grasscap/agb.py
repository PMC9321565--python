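"""Aboveground biomass available to grazers.

Annual net primary productivity (NPP, g C m⁻² yr⁻¹) is partitioned into its
aboveground fraction with a linear function of mean annual temperature
(MAT), converted from carbon to dry-matter units, and then reduced by two
geographic restrictions: tree canopy shading of the understory and terrain
slope (steep terrain is grazed less to avoid erosion).  The chain is

    AGB = NPP · f_ANPP / carbon_factor · TreeCoverMultiplier · SlopesMultiplier

with

    f_ANPP = 0.171 + 0.0129 · MAT            (MAT in °C)
    TreeCoverMultiplier = exp(−4.45521 · x)  (x = canopy-cover fraction)

and SlopesMultiplier a step function of slope steepness (%).  Cells where
f_ANPP ≤ 0 (MAT below ≈ −13.26 °C) are excluded — the linear partitioning
model has no support there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Grid

FANPP_INTERCEPT = 0.171
FANPP_SLOPE = 0.0129  # per °C
TREE_DECAY = 4.45521
CARBON_FACTOR = 0.475  # g C per g dry biomass; conventional value in [0.47, 0.50]


@dataclass
class SlopeReclassTable:
    """Step function mapping slope steepness (%) to a feed-efficiency multiplier.

    Each ``(upper_bound, multiplier)`` pair applies to slopes up to and
    including the bound (boundary values belong to the gentler class).  The
    default four-class scheme follows standard rangeland utilisation
    recommendations: flat terrain is fully usable, and usability drops to
    zero above 60 % slope.
    """

    entries: tuple[tuple[float, float], ...] = (
        (10.0, 1.0),
        (30.0, 0.7),
        (60.0, 0.4),
        (np.inf, 0.0),
    )

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.entries]
        mults = [m for _, m in self.entries]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("slope bounds must be strictly increasing")
        if any(m2 > m1 for m1, m2 in zip(mults, mults[1:])):
            raise ValueError("multipliers must be non-increasing with slope")
        if not all(0.0 <= m <= 1.0 for m in mults):
            raise ValueError("multipliers must lie in [0, 1]")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([b for b, _ in self.entries])

    @property
    def multipliers(self) -> np.ndarray:
        return np.array([m for _, m in self.entries])


@dataclass
class AGBParams:
    """Parameters of the NPP → AGB chain."""

    fanpp_intercept: float = FANPP_INTERCEPT
    fanpp_slope: float = FANPP_SLOPE
    tree_decay: float = TREE_DECAY
    carbon_factor: float = CARBON_FACTOR
    slope_reclass: SlopeReclassTable = field(default_factory=SlopeReclassTable)

    def __post_init__(self) -> None:
        if not 0.0 < self.carbon_factor <= 1.0:
            raise ValueError("carbon_factor must be in (0, 1]")
        if self.tree_decay <= 0:
            raise ValueError("tree_decay must be positive")

    @property
    def fanpp_zero_mat(self) -> float:
        """MAT (°C) at which the aboveground fraction crosses zero."""
        return -self.fanpp_intercept / self.fanpp_slope


def fanpp(mat_grid: Grid, params: AGBParams | None = None) -> Grid:
    """Aboveground fraction of NPP from mean annual temperature (°C).

    Cells where the fraction is ≤ 0 are set to nodata: they fall outside
    the domain of the partitioning model and are excluded downstream.
    """
    params = params or AGBParams()
    mat = mat_grid.masked()
    f = params.fanpp_intercept + params.fanpp_slope * mat
    f[f <= 0] = np.nan
    return mat_grid.like(f)


def tree_cover_multiplier(canopy_grid: Grid, params: AGBParams | None = None) -> Grid:
    """Fraction of NPP reaching the understory under canopy-cover fraction x.

    exp(−k·x): equals 1 on open ground and decays to ≈ 0.012 under closed
    canopy.  Canopy values outside [0, 1] are rejected.
    """
    params = params or AGBParams()
    x = canopy_grid.masked()
    finite = np.isfinite(x)
    if np.any((x[finite] < 0) | (x[finite] > 1)):
        raise ValueError("canopy cover fraction must lie in [0, 1]")
    return canopy_grid.like(np.exp(-params.tree_decay * x))


def slope_multiplier(slope_grid: Grid, table: SlopeReclassTable | None = None) -> Grid:
    """Feed-efficiency multiplier from terrain slope (%), by table lookup."""
    table = table or SlopeReclassTable()
    s = slope_grid.masked()
    finite = np.isfinite(s)
    if np.any(s[finite] < 0):
        raise ValueError("slope must be non-negative (percent)")
    # side='left': a slope exactly on a bound falls in the gentler class
    idx = np.searchsorted(table.bounds, np.where(finite, s, 0.0), side="left")
    out = table.multipliers[idx].astype(float)
    out[~finite] = np.nan
    return slope_grid.like(out)


def compute_agb(
    npp_grid: Grid,
    mat_grid: Grid,
    canopy_grid: Grid,
    slope_grid: Grid,
    params: AGBParams | None = None,
) -> Grid:
    """Aboveground biomass available for grazing (g dry matter m⁻² yr⁻¹).

    All inputs must be on the same geometry.  Nodata in any input — in
    particular the temperature exclusion applied inside :func:`fanpp` —
    propagates to the output.
    """
    params = params or AGBParams()
    for other in (mat_grid, canopy_grid, slope_grid):
        if not npp_grid.same_geometry(other):
            raise ValueError("AGB inputs must share geometry; harmonize first")
    f = fanpp(mat_grid, params).values
    tree = tree_cover_multiplier(canopy_grid, params).values
    slope = slope_multiplier(slope_grid, params.slope_reclass).values
    agb = npp_grid.masked() * f / params.carbon_factor * tree * slope
    return npp_grid.like(agb)
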