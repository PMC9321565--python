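"""Land-cover compositing, grassland masking, and grid harmonization.

Land-cover classes follow the IGBP coding; the grass-bearing classes are
woody savannas (8), savannas (9) and grasslands (10).  Because a pixel's
class can flip between years, the analysis uses the modal (most frequent)
class over the study period.  Sparse ancillary layers (canopy cover is
mapped only in anchor years) are linearly interpolated to the full annual
range, and everything is resampled onto the geometry of the NPP layer
before any arithmetic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .grids import AnnualStack, Grid

GRASSLAND_CLASSES = frozenset({8, 9, 10})  # woody savannas, savannas, grasslands


def mode_landcover(stack: AnnualStack) -> Grid:
    """Per-pixel modal land-cover class over the stack years.

    Ties are broken toward the smallest class code (deterministic).  Cells
    with no valid class in any year are nodata.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    for _, g in stack:
        if g.is_float:
            raise ValueError("land-cover layers must be integer-coded")
    ref = stack.geometry
    arr = np.stack([g.values for g in stack.layers])  # (T, H, W) ints
    valid = np.stack([g.valid_mask for g in stack.layers])
    classes = np.unique(arr[valid]) if valid.any() else np.array([], dtype=arr.dtype)
    if classes.size == 0:
        return Grid(
            np.full(ref.shape, ref.nodata, dtype=np.int64),
            ref.transform, ref.crs, nodata=ref.nodata,
        )
    counts = np.stack([((arr == c) & valid).sum(axis=0) for c in classes])
    # argmax takes the first maximum; classes are sorted ascending, so the
    # smallest code wins ties
    mode = classes[np.argmax(counts, axis=0)].astype(np.int64)
    mode[~valid.any(axis=0)] = ref.nodata
    return Grid(mode, ref.transform, ref.crs, nodata=int(ref.nodata))


def grassland_mask(mode_grid: Grid, class_set: Sequence[int] | frozenset = GRASSLAND_CLASSES) -> Grid:
    """Boolean grid: True where the modal class is a grass-bearing class."""
    class_set = set(int(c) for c in class_set)
    if not class_set:
        raise ValueError("empty grassland class set")
    mask = np.isin(mode_grid.values, sorted(class_set)) & mode_grid.valid_mask
    return Grid(mask, mode_grid.transform, mode_grid.crs, nodata=0)


def interpolate_annual(sparse_stack: AnnualStack, target_years: Sequence[int]) -> AnnualStack:
    """Linearly interpolate a stack with anchor years onto all target years.

    Exact at anchors; target years outside the anchor range take the nearest
    anchor's values (constant extension).  The interpolation weights depend
    only on the year, so each output layer is a convex combination of the
    two bracketing anchors.
    """
    if len(sparse_stack) == 0:
        raise ValueError("no anchor years to interpolate from")
    anchors = np.asarray(sparse_stack.years, dtype=float)
    arr = sparse_stack.to_array()
    template = sparse_stack.geometry
    out_layers = []
    target_years = sorted(int(y) for y in target_years)
    for year in target_years:
        t = float(year)
        if t <= anchors[0]:
            vals = arr[0].copy()
        elif t >= anchors[-1]:
            vals = arr[-1].copy()
        else:
            hi = int(np.searchsorted(anchors, t, side="left"))
            if anchors[hi] == t:
                vals = arr[hi].copy()
            else:
                lo = hi - 1
                w = (t - anchors[lo]) / (anchors[hi] - anchors[lo])
                vals = (1.0 - w) * arr[lo] + w * arr[hi]
        out_layers.append(template.like(vals))
    return AnnualStack(years=target_years, layers=out_layers)


def _overlap_weights(
    src_origin: float, src_res: float, n_src: int,
    dst_origin: float, dst_res: float, n_dst: int,
) -> np.ndarray:
    """(n_dst, n_src) matrix of 1-D cell-interval overlap lengths."""
    src_edges = src_origin + src_res * np.arange(n_src + 1)
    dst_edges = dst_origin + dst_res * np.arange(n_dst + 1)
    src_lo = np.minimum(src_edges[:-1], src_edges[1:])
    src_hi = np.maximum(src_edges[:-1], src_edges[1:])
    dst_lo = np.minimum(dst_edges[:-1], dst_edges[1:])
    dst_hi = np.maximum(dst_edges[:-1], dst_edges[1:])
    lo = np.maximum(dst_lo[:, None], src_lo[None, :])
    hi = np.minimum(dst_hi[:, None], src_hi[None, :])
    return np.clip(hi - lo, 0.0, None)


def resample_to_reference(grid: Grid, reference: Grid, kind: str = "continuous") -> Grid:
    """Resample a grid onto the reference geometry (axis-aligned, same CRS).

    ``continuous`` uses the exact area-weighted mean of overlapping source
    cells (nodata excluded from the average); ``categorical`` takes the
    source cell nearest to each reference cell centre.
    """
    if kind not in {"continuous", "categorical"}:
        raise ValueError(f"unknown resampling kind {kind!r}")
    if grid.crs != reference.crs:
        raise ValueError("resampling across CRSs is not supported")
    if grid.same_geometry(reference):
        return reference.like(grid.values.copy(), nodata=grid.nodata)
    xmin_s, ymin_s, xmax_s, ymax_s = grid.bounds()
    xmin_r, ymin_r, xmax_r, ymax_r = reference.bounds()
    if xmax_s <= xmin_r or xmax_r <= xmin_s or ymax_s <= ymin_r or ymax_r <= ymin_s:
        raise ValueError("source and reference extents are disjoint")

    if kind == "categorical":
        xs_r, ys_r = reference.cell_centers()
        x0, dx, _, y0, _, dy = grid.transform
        cols = np.clip(np.floor((xs_r - x0) / dx).astype(int), 0, grid.shape[1] - 1)
        rows = np.clip(np.floor((ys_r - y0) / dy).astype(int), 0, grid.shape[0] - 1)
        vals = grid.values[np.ix_(rows, cols)].copy()
        return Grid(vals, reference.transform, reference.crs, nodata=grid.nodata)

    w_rows = _overlap_weights(
        grid.transform[3], grid.transform[5], grid.shape[0],
        reference.transform[3], reference.transform[5], reference.shape[0],
    )
    w_cols = _overlap_weights(
        grid.transform[0], grid.transform[1], grid.shape[1],
        reference.transform[0], reference.transform[1], reference.shape[1],
    )
    vals = grid.masked()
    valid = np.isfinite(vals)
    filled = np.where(valid, vals, 0.0)
    num = w_rows @ filled @ w_cols.T
    den = w_rows @ valid.astype(float) @ w_cols.T
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return Grid(out, reference.transform, reference.crs, nodata=grid.nodata)
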