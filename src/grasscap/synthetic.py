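"""Synthetic input bundles with the statistical structure the analysis assumes.

The generator emulates the seven gridded inputs of the carrying-capacity
analysis — annual NPP, mean annual temperature, tree canopy cover, terrain
slope, categorical land cover, species headcount densities, and a
livestock-production-system mask — on one shared geometry, together with
the ground truth needed to test every downstream stage.

The NPP process is multiplicative:

    NPP(x, y, t) = base(x, y) · (1 + β(x, y) · t) · ε_t,
    ε_t ~ lognormal(0, σ²) i.i.d. per pixel and year,

so productivity stays positive and the interannual noise is right-skewed,
matching how variability is later measured (coefficient of variation).
Spatial smoothness comes from separable moving-average filtering of white
noise.  Livestock headcounts are constructed backwards from a per-pixel
target stocking ratio so that the low / medium / overstocked classes are
known by construction: a target relative stocking density is drawn inside
one of the three class intervals (kept clear of the 0.20 / 0.65 boundaries),
multiplied by the point-parameter carrying capacity, and split into species
headcounts with gamma-weighted shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

from . import io as gio
from .agb import AGBParams, compute_agb
from .grids import AnnualStack, Grid, nanmedian
from .landcover import GRASSLAND_CLASSES, interpolate_annual
from .stocking import (
    CLASS_LOW,
    CLASS_MEDIUM,
    CLASS_NODATA,
    CLASS_OVERSTOCKED,
    DEFAULT_AU_FACTORS,
    AnimalUnitParams,
    RSDClassScheme,
    carrying_capacity,
)

#: target-RSD sampling intervals per class, kept clear of the class
#: boundaries so float round-off cannot flip a constructed label
_CLASS_INTERVALS = {
    CLASS_LOW: (0.02, 0.18),
    CLASS_MEDIUM: (0.22, 0.63),
    CLASS_OVERSTOCKED: (0.67, 1.50),
}


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic world; defaults give a desk-scale analogue
    of the 2001–2015 study setup."""

    rows: int = 64
    cols: int = 64
    years: tuple[int, ...] = tuple(range(2001, 2016))
    crs: str = "EPSG:6933"
    cell_size: float = 500.0  # metres

    # NPP process (g C m⁻² yr⁻¹)
    npp_mean: float = 300.0
    npp_spatial_sd: float = 60.0
    smoothness: int = 7  # moving-average window (cells)
    beta_mean: float = 0.0  # fractional trend per year
    beta_sd: float = 0.01
    noise_sigma: float = 0.1  # lognormal sigma of interannual noise

    # temperature field (°C)
    mat_mean: float = 10.0
    mat_gradient: float = 10.0  # north-to-south span
    mat_noise_sd: float = 2.0
    mat_npp_coupling: float = 1.5  # °C per sd of the NPP base anomaly

    # canopy cover fraction and its anchor-year drift
    canopy_mean: float = 0.15
    canopy_sd: float = 0.15
    canopy_max: float = 0.8
    canopy_anchor_years: tuple[int, ...] = (2001, 2005, 2010, 2015)
    canopy_drift: float = 0.002  # fraction per year, applied before clipping

    # terrain slope (%)
    slope_median: float = 8.0
    slope_spread: float = 0.9  # lognormal-style spread of the slope field

    # land cover
    grassland_fraction: float = 0.7
    grassland_classes: tuple[int, ...] = tuple(sorted(GRASSLAND_CLASSES))
    filler_classes: tuple[int, ...] = (12, 13)
    landcover_flip_rate: float = 0.08  # per-pixel-year chance of a spurious class

    # livestock construction
    class_probabilities: tuple[float, float, float] = (0.42, 0.28, 0.30)
    species_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "cattle": 0.55, "sheep": 0.20, "goat": 0.10, "horse": 0.10, "buffalo": 0.05,
        }
    )
    share_concentration: float = 8.0  # gamma shape scale for per-pixel shares
    production_system_fraction: float = 0.6
    rsd_window: tuple[int, ...] = (2008, 2009, 2010, 2011, 2012)

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2×2")
        if not 0 < self.grassland_fraction <= 1:
            raise ValueError("grassland fraction must be in (0, 1]")
        if self.noise_sigma < 0 or self.beta_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if not 0 <= self.canopy_mean <= 1 or not 0 < self.canopy_max <= 1:
            raise ValueError("canopy parameters must stay in [0, 1]")
        if abs(sum(self.class_probabilities) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")

    @property
    def transform(self) -> tuple[float, ...]:
        return (0.0, self.cell_size, 0.0, 0.0, 0.0, -self.cell_size)


@dataclass
class ScenarioTruth:
    """Ground truth recomputable from config + seed: the planted trend field,
    the noise-free NPP stack, the implied animal-unit density, and the
    stocking-pressure class each pixel was built to land in."""

    beta: Grid
    npp_noise_free: AnnualStack
    au_density: Grid
    class_labels: Grid
    target_rsd: Grid
    grassland_mask: Grid
    landcover_base: Grid


@dataclass
class ScenarioBundle:
    """All seven input layers plus the truth."""

    npp_stack: AnnualStack
    mat: Grid
    canopy_anchors: AnnualStack
    slope: Grid
    landcover_stack: AnnualStack
    headcounts: dict[str, Grid]
    system_mask: Grid
    truth: ScenarioTruth
    config: ScenarioConfig


def _smooth_field(rng: np.random.Generator, shape, window: int) -> np.ndarray:
    """Standardised spatially autocorrelated field (zero mean, unit sd)."""
    white = rng.standard_normal(shape)
    if window > 1:
        sm = ndimage.uniform_filter(white, size=window, mode="reflect")
    else:
        sm = white
    sm = sm - sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_scenario(config: ScenarioConfig | None = None) -> ScenarioBundle:
    """Build a complete, internally consistent synthetic input bundle.

    Deterministic for a fixed ``config.rng_seed``.
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed))
    shape = (cfg.rows, cfg.cols)
    template = Grid(np.zeros(shape), cfg.transform, cfg.crs)
    years = list(cfg.years)
    t_idx = np.arange(len(years), dtype=float)

    # -- NPP base, trend, noise --------------------------------------------
    z_npp = _smooth_field(rng, shape, cfg.smoothness)
    base = cfg.npp_mean + cfg.npp_spatial_sd * z_npp
    if np.any(base <= 0):
        raise ValueError("non-positive base NPP; reduce npp_spatial_sd")
    beta = cfg.beta_mean + cfg.beta_sd * _smooth_field(rng, shape, cfg.smoothness)
    growth = 1.0 + beta[None, :, :] * t_idx[:, None, None]
    if np.any(growth <= 0):
        raise ValueError("trend drives NPP non-positive within the study period")
    clean = base[None, :, :] * growth
    if cfg.noise_sigma > 0:
        eps = np.exp(cfg.noise_sigma * rng.standard_normal((len(years), *shape)))
    else:
        eps = np.ones((len(years), *shape))
    npp_stack = AnnualStack.from_array(years, clean * eps, template)

    # -- temperature --------------------------------------------------------
    row_frac = (np.arange(cfg.rows) + 0.5) / cfg.rows
    mat = (
        cfg.mat_mean
        + cfg.mat_gradient * (row_frac[:, None] - 0.5) * np.ones(shape)
        + cfg.mat_npp_coupling * z_npp
        + cfg.mat_noise_sd * _smooth_field(rng, shape, cfg.smoothness)
    )
    mat_grid = template.like(mat)

    # -- canopy anchors ------------------------------------------------------
    canopy0 = np.clip(
        cfg.canopy_mean + cfg.canopy_sd * _smooth_field(rng, shape, cfg.smoothness),
        0.0, cfg.canopy_max,
    )
    anchor_years = sorted(cfg.canopy_anchor_years)
    anchor_layers = []
    for ay in anchor_years:
        drifted = np.clip(canopy0 + cfg.canopy_drift * (ay - years[0]), 0.0, cfg.canopy_max)
        anchor_layers.append(template.like(drifted))
    canopy_anchors = AnnualStack(years=anchor_years, layers=anchor_layers)

    # -- slope ---------------------------------------------------------------
    slope = cfg.slope_median * np.exp(
        cfg.slope_spread * _smooth_field(rng, shape, cfg.smoothness)
    )
    slope_grid = template.like(slope)

    # -- land cover ----------------------------------------------------------
    suitability = _smooth_field(rng, shape, cfg.smoothness) + 1e-9 * rng.standard_normal(shape)
    n_cells = cfg.rows * cfg.cols
    n_grass = int(round(cfg.grassland_fraction * n_cells))
    order = np.argsort(suitability.ravel())[::-1]
    grass_flat = np.zeros(n_cells, dtype=bool)
    grass_flat[order[:n_grass]] = True
    grass = grass_flat.reshape(shape)

    base_lc = np.empty(shape, dtype=np.int64)
    gclasses = list(cfg.grassland_classes)
    # denser canopy → woodier grassland class
    canopy_rank = canopy0 + 1e-9 * rng.standard_normal(shape)
    edges = np.quantile(canopy_rank[grass], np.linspace(0, 1, len(gclasses) + 1)[1:-1]) \
        if n_grass else np.array([])
    gidx = np.searchsorted(edges, canopy_rank, side="left") if edges.size else np.zeros(shape, int)
    # low canopy → grasslands (10), high canopy → woody savannas (8)
    by_openness = np.asarray(sorted(gclasses, reverse=True))
    base_lc[grass] = by_openness[gidx[grass]] if len(gclasses) > 1 else gclasses[0]
    fill = rng.integers(0, len(cfg.filler_classes), size=shape)
    base_lc[~grass] = np.asarray(cfg.filler_classes)[fill[~grass]]

    # annual layers: base map with capped spurious flips so the mode is the base
    n_years = len(years)
    flips = rng.random((n_years, *shape)) < cfg.landcover_flip_rate
    too_many = flips.sum(axis=0) > (n_years - 1) // 2
    flips[:, too_many] = False
    all_classes = np.array(sorted(set(gclasses) | set(cfg.filler_classes)))
    lc_layers = []
    for yi in range(n_years):
        lc = base_lc.copy()
        f = flips[yi]
        if f.any():
            offs = rng.integers(1, len(all_classes), size=int(f.sum()))
            pos = np.searchsorted(all_classes, lc[f])
            lc[f] = all_classes[(pos + offs) % len(all_classes)]
        lc_layers.append(Grid(lc, cfg.transform, cfg.crs, nodata=-1))
    landcover_stack = AnnualStack(years=years, layers=lc_layers)

    # -- point-parameter capacity on grassland (for livestock construction) --
    canopy_annual = interpolate_annual(canopy_anchors, years)
    agb_params = AGBParams()
    au_params = AnimalUnitParams()
    window = [y for y in cfg.rsd_window if y in years] or years
    cc_window = []
    agb_window = []
    for y in window:
        npp_y = npp_stack[y]
        npp_masked = npp_y.like(np.where(grass, npp_y.values, np.nan))
        agb = compute_agb(npp_masked, mat_grid, canopy_annual[y], slope_grid, agb_params)
        agb_window.append(agb.masked())
        cc_window.append(carrying_capacity(agb, au_params).masked())
    cc_med = nanmedian(np.stack(cc_window), axis=0)
    agb_med = nanmedian(np.stack(agb_window), axis=0)

    # -- livestock headcounts built backwards from target stocking ratios ----
    labels = np.full(shape, CLASS_NODATA, dtype=np.int64)
    target = np.full(shape, np.nan)
    # the same display floor the pipeline applies (AGB > 0.1 g m⁻² yr⁻¹)
    classifiable = grass & np.isfinite(cc_med) & (cc_med > 0) & (agb_med > 0.1)
    n_cls = int(classifiable.sum())
    drawn = rng.choice(
        [CLASS_LOW, CLASS_MEDIUM, CLASS_OVERSTOCKED],
        size=n_cls, p=list(cfg.class_probabilities),
    )
    vals = np.empty(n_cls)
    for cls, (lo, hi) in _CLASS_INTERVALS.items():
        sel = drawn == cls
        vals[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
    labels[classifiable] = drawn
    target[classifiable] = vals

    au_total = np.zeros(shape)
    au_total[classifiable] = vals * cc_med[classifiable]
    # a little background stock outside the classifiable area
    background = ~classifiable
    au_total[background] = rng.gamma(1.5, 2.0, size=int(background.sum()))

    shares_raw = {
        s: rng.gamma(cfg.share_concentration * w, 1.0, size=shape)
        for s, w in cfg.species_shares.items()
    }
    share_sum = sum(shares_raw.values())
    headcounts = {}
    for s, raw in shares_raw.items():
        share = raw / share_sum
        headcounts[s] = template.like(share * au_total / DEFAULT_AU_FACTORS[s])

    # -- production-system mask ----------------------------------------------
    sys_field = _smooth_field(rng, shape, cfg.smoothness)
    thresh = np.quantile(sys_field, 1.0 - cfg.production_system_fraction)
    system_mask = Grid(
        (sys_field >= thresh).astype(np.int64), cfg.transform, cfg.crs, nodata=-1
    )

    truth = ScenarioTruth(
        beta=template.like(beta),
        npp_noise_free=AnnualStack.from_array(years, clean, template),
        au_density=template.like(au_total),
        class_labels=Grid(labels, cfg.transform, cfg.crs, nodata=CLASS_NODATA),
        target_rsd=template.like(target),
        grassland_mask=Grid(grass.astype(np.int64), cfg.transform, cfg.crs, nodata=-1),
        landcover_base=Grid(base_lc, cfg.transform, cfg.crs, nodata=-1),
    )
    return ScenarioBundle(
        npp_stack=npp_stack,
        mat=mat_grid,
        canopy_anchors=canopy_anchors,
        slope=slope_grid,
        landcover_stack=landcover_stack,
        headcounts=headcounts,
        system_mask=system_mask,
        truth=truth,
        config=cfg,
    )


def write_fixture(bundle: ScenarioBundle, directory: str | Path) -> dict[str, str]:
    """Write every bundle layer in formats the readers understand.

    Returns a manifest mapping layer names to file names.  Regenerating the
    bundle from the recorded seed and rewriting produces byte-identical
    files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    gio.write_stack(bundle.npp_stack, directory / "npp.nc")
    manifest["npp_stack"] = "npp.nc"
    gio.write_raster(bundle.mat, directory / "mat.asc")
    manifest["mat"] = "mat.asc"
    gio.write_stack(bundle.canopy_anchors, directory / "canopy_anchors.nc")
    manifest["canopy_anchors"] = "canopy_anchors.nc"
    gio.write_raster(bundle.slope, directory / "slope.asc")
    manifest["slope"] = "slope.asc"
    gio.write_stack(bundle.landcover_stack, directory / "landcover.nc")
    manifest["landcover_stack"] = "landcover.nc"
    for species, grid in bundle.headcounts.items():
        name = f"headcount_{species}.asc"
        gio.write_raster(grid, directory / name)
        manifest[f"headcount_{species}"] = name
    gio.write_raster(bundle.system_mask, directory / "system_mask.asc")
    manifest["system_mask"] = "system_mask.asc"

    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    gio.write_raster(bundle.truth.beta, truth_dir / "beta.asc")
    gio.write_stack(bundle.truth.npp_noise_free, truth_dir / "npp_noise_free.nc")
    gio.write_raster(bundle.truth.au_density, truth_dir / "au_density.asc")
    gio.write_raster(bundle.truth.class_labels, truth_dir / "class_labels.asc")
    gio.write_raster(bundle.truth.grassland_mask, truth_dir / "grassland_mask.asc")
    manifest["truth"] = "truth/"
    return manifest
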