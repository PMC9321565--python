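"""End-to-end pipeline: inputs → AGB → CC → RSD → trends → uncertainty.

Stages mirror the analysis flow: harmonize every layer onto the NPP
geometry, composite the modal land cover and mask to grassland, interpolate
sparse canopy anchors to all study years, compute annual AGB and CC at
point parameters, derive stocking-density products against the 2008–2012
median window, run trend/variability statistics on the CC stack, and
propagate parameter uncertainty by Monte Carlo.  Every artifact is written
under the configured output directory and listed in ``manifest.json``; the
run is deterministic for a fixed configuration and seed.

A stage-level logger reports how many cells each mask retains, since the
area surviving each filter is itself a result of interest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as gio
from .agb import compute_agb
from .config import RunConfig
from .grids import AnnualStack, Grid, nanmedian
from .landcover import (
    grassland_mask,
    interpolate_annual,
    mode_landcover,
    resample_to_reference,
)
from .stocking import (
    CLASS_LABELS,
    AnimalUnitParams,
    RSDClassScheme,
    animal_units,
    carrying_capacity,
    classify_rsd,
    mask_livestock_grazing,
    median_rsd_window,
    overstocked_year_fraction,
    rsd_min_cc,
)
from .trends import interannual_cv, min_median_ratio, pixel_trend, zonal_summary
from .uncertainty import propagate

log = logging.getLogger("grasscap.pipeline")

DEFAULT_WINDOW = (2008, 2009, 2010, 2011, 2012)

#: species file stem → species key
_SPECIES = ("cattle", "buffalo", "sheep", "goat", "horse")


class PipelineError(RuntimeError):
    """Raised when inputs cannot be reconciled (e.g. geometry mismatch)."""


@dataclass
class PipelineInputs:
    npp_stack: AnnualStack
    mat: Grid
    canopy_anchors: AnnualStack
    slope: Grid
    landcover_stack: AnnualStack
    headcounts: dict[str, Grid]
    system_mask: Grid


def load_inputs(input_dir: str | Path) -> PipelineInputs:
    """Load a scenario directory laid out by ``synthetic.write_fixture``."""
    d = Path(input_dir)
    headcounts = {
        sp: gio.read_raster(d / f"headcount_{sp}.asc")
        for sp in _SPECIES
        if (d / f"headcount_{sp}.asc").exists()
    }
    if not headcounts:
        raise PipelineError(f"no headcount layers found under {d}")
    return PipelineInputs(
        npp_stack=gio.read_stack(d / "npp.nc"),
        mat=gio.read_raster(d / "mat.asc"),
        canopy_anchors=gio.read_stack(d / "canopy_anchors.nc"),
        slope=gio.read_raster(d / "slope.asc"),
        landcover_stack=gio.read_stack(d / "landcover.nc"),
        headcounts=headcounts,
        system_mask=gio.read_raster(d / "system_mask.asc"),
    )


def harmonize(inputs: PipelineInputs) -> PipelineInputs:
    """Resample every layer onto the NPP geometry (the analysis grid)."""
    ref = inputs.npp_stack.geometry

    def _cont(g: Grid) -> Grid:
        return resample_to_reference(g, ref, "continuous")

    def _cat(g: Grid) -> Grid:
        return resample_to_reference(g, ref, "categorical")

    out = PipelineInputs(
        npp_stack=inputs.npp_stack,
        mat=_cont(inputs.mat),
        canopy_anchors=inputs.canopy_anchors.map(_cont),
        slope=_cont(inputs.slope),
        landcover_stack=inputs.landcover_stack.map(_cat),
        headcounts={sp: _cont(g) for sp, g in inputs.headcounts.items()},
        system_mask=_cat(inputs.system_mask),
    )
    for name, g in (
        ("mat", out.mat), ("slope", out.slope), ("system_mask", out.system_mask),
    ):
        if not g.same_geometry(ref):
            raise PipelineError(f"{name} could not be harmonized to the NPP grid")
    return out


def _log_mask(name: str, mask: np.ndarray) -> None:
    log.info("%s: %d cells retained / %d masked", name, int(mask.sum()), int((~mask).sum()))


@dataclass
class PipelineResult:
    manifest: dict[str, str]
    output_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write the artifact bundle.

    Returns the manifest (artifact name → file name).  Deterministic for a
    fixed config + seed: rerunning yields bit-identical tables and rasters.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str, obj, filename: str) -> None:
        if isinstance(obj, AnnualStack):
            gio.write_stack(obj, out_dir / filename)
        else:
            gio.write_raster(obj, out_dir / filename)
        manifest[name] = filename

    inputs = harmonize(load_inputs(config.input_dir))
    years = config.years or list(inputs.npp_stack.years)
    npp_stack = inputs.npp_stack.select(years)
    window = config.window_years or [y for y in DEFAULT_WINDOW if y in years] or years
    scheme = RSDClassScheme(*config.class_thresholds)
    log.info("stage base: %d years, window %s", len(years), window)

    # -- land cover and grassland mask --------------------------------------
    mode = mode_landcover(inputs.landcover_stack.select(years))
    gmask = grassland_mask(mode, config.grassland_classes)
    grass = gmask.values.astype(bool)
    _log_mask("grassland mask", grass)
    emit("landcover_mode", mode, "landcover_mode.asc")
    emit("grassland_mask", gmask, "grassland_mask.asc")

    # -- annual AGB and CC at point parameters ------------------------------
    canopy_annual = interpolate_annual(inputs.canopy_anchors, years)
    au_params = AnimalUnitParams()
    agb_layers, cc_layers = [], []
    for y in years:
        npp_y = npp_stack[y]
        npp_masked = npp_y.like(np.where(grass, npp_y.values, np.nan))
        agb = compute_agb(npp_masked, inputs.mat, canopy_annual[y], inputs.slope, config.agb)
        agb_layers.append(agb)
        cc_layers.append(carrying_capacity(agb, au_params))
    agb_stack = AnnualStack(years=years, layers=agb_layers)
    cc_stack = AnnualStack(years=years, layers=cc_layers)
    template = npp_stack.geometry

    agb_med = nanmedian(agb_stack.select(window).to_array(), axis=0)
    cc_med = nanmedian(cc_stack.select(window).to_array(), axis=0)
    display = np.isfinite(agb_med) & (agb_med > config.agb_floor)
    _log_mask("display floor (AGB > %.3g)" % config.agb_floor, display)

    def _displayed(values: np.ndarray) -> Grid:
        vals = np.asarray(values, dtype=float).copy()
        vals[~display] = np.nan
        return template.like(vals)

    emit("agb_stack", agb_stack, "agb.nc")
    emit("cc_stack", cc_stack, "cc.nc")
    emit("agb_median", _displayed(agb_med), "agb_median.asc")
    emit("cc_median", _displayed(cc_med), "cc_median.asc")

    # -- stocking density ----------------------------------------------------
    au = animal_units(inputs.headcounts, config.au_factors)
    rsd_med = median_rsd_window(au, cc_stack, window)
    classes = classify_rsd(_displayed(rsd_med.values), scheme)
    rsd_min = rsd_min_cc(au, cc_stack)
    over_frac = overstocked_year_fraction(au, cc_stack, scheme)
    emit("animal_units", au, "animal_units.asc")
    emit("rsd_median", _displayed(rsd_med.values), "rsd_median.asc")
    emit("rsd_classes", classes, "rsd_classes.asc")
    emit("rsd_min_cc", _displayed(rsd_min.values), "rsd_min_cc.asc")
    emit("overstocked_year_fraction", _displayed(over_frac.values),
         "overstocked_year_fraction.asc")
    labels_csv = out_dir / "rsd_class_labels.csv"
    with open(labels_csv, "w") as fh:
        fh.write("code,label\n")
        for code, label in sorted(CLASS_LABELS.items()):
            fh.write(f"{code},{label}\n")
    manifest["rsd_class_labels"] = labels_csv.name

    # -- livestock-grazing system subset -------------------------------------
    cc_grazing = mask_livestock_grazing(_displayed(cc_med), inputs.system_mask)
    rsd_grazing = mask_livestock_grazing(_displayed(rsd_med.values), inputs.system_mask)
    _log_mask("livestock-grazing system", inputs.system_mask.values.astype(bool))
    emit("cc_median_grazing", cc_grazing, "cc_median_grazing.asc")
    emit("rsd_median_grazing", rsd_grazing, "rsd_median_grazing.asc")

    # -- trends and variability ----------------------------------------------
    trend = pixel_trend(cc_stack, alpha=config.alpha)
    emit("cc_trend_slope", trend.slope, "cc_trend_slope.asc")
    emit("cc_trend_p", trend.p_value, "cc_trend_p.asc")
    emit("cc_trend_scaled", trend.scaled_change, "cc_trend_scaled.asc")
    emit("cc_interannual_cv", interannual_cv(cc_stack), "cc_interannual_cv.asc")
    emit("cc_min_median_ratio", min_median_ratio(cc_stack), "cc_min_median_ratio.asc")

    zonal = zonal_summary(cc_stack, mode, statistic="mean")
    zonal_path = out_dir / "cc_zonal.csv"
    zonal.to_csv(zonal_path, index=False, float_format="%.9g")
    manifest["cc_zonal"] = zonal_path.name

    # -- Monte-Carlo uncertainty ---------------------------------------------
    npp_grass = npp_stack.map(lambda g: g.like(np.where(grass, g.values, np.nan)))
    summaries = propagate(
        npp_grass, inputs.mat,
        canopy_annual[window[len(window) // 2]], inputs.slope,
        inputs.headcounts, config.param_specs,
        n=config.n_draws, seed=config.rng_seed,
        window_years=window, agb_params=config.agb,
    )
    for var, summary in summaries.items():
        emit(f"mc_{var}_median", summary.median, f"mc_{var}_median.asc")
        emit(f"mc_{var}_cv", summary.cv, f"mc_{var}_cv.asc")

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline wrote %d artifacts to %s", len(manifest), out_dir)
    return PipelineResult(manifest=manifest, output_dir=out_dir)
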