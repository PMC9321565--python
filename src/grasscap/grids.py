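"""Core raster containers.

A :class:`Grid` is a single 2-D georeferenced layer; an :class:`AnnualStack`
is an ordered sequence of grids on identical geometry, one per year.  These
are the universal currency of the pipeline: every per-pixel quantity (NPP,
mean annual temperature, canopy cover, biomass, carrying capacity, stocking
density) travels as one of them.

Conventions
-----------
* The geotransform is the GDAL-order 6-tuple
  ``(x_origin, x_res, x_skew, y_origin, y_skew, y_res)`` with ``y_res``
  normally negative (row 0 is the northern edge).
* Continuous grids store ``float`` values with ``NaN`` marking nodata
  internally; the ``nodata`` attribute records the sentinel used on disk.
* Categorical grids (land cover, zones, class labels) store integers with
  the ``nodata`` sentinel in-band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

DEFAULT_NODATA = -9999.0


def nanmedian(arr: np.ndarray, axis: int = 0) -> np.ndarray:
    """np.nanmedian with the all-NaN-slice warning silenced (all-NaN → NaN)."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        return np.nanmedian(arr, axis=axis)


def nanmin(arr: np.ndarray, axis: int = 0) -> np.ndarray:
    """np.nanmin with the all-NaN-axis warning silenced (all-NaN → NaN)."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN")
        return np.nanmin(arr, axis=axis)


@dataclass
class Grid:
    """One 2-D georeferenced raster layer with nodata handling."""

    values: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    crs: str
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"Grid values must be 2-D, got shape {self.values.shape}")
        self.transform = tuple(float(t) for t in self.transform)
        if len(self.transform) != 6:
            raise ValueError("transform must be a 6-tuple geotransform")
        if not self.crs:
            raise ValueError("Grid requires a CRS identifier")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_res(self) -> float:
        return self.transform[1]

    @property
    def y_res(self) -> float:
        return self.transform[5]

    @property
    def cell_area(self) -> float:
        """Cell area in squared map units (ignores skew terms)."""
        return abs(self.x_res * self.y_res)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x_centers, y_centers) 1-D coordinate arrays."""
        x0, dx, _, y0, _, dy = self.transform
        nrow, ncol = self.shape
        xs = x0 + dx * (np.arange(ncol) + 0.5)
        ys = y0 + dy * (np.arange(nrow) + 0.5)
        return xs, ys

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) extent, axis-aligned grids only."""
        x0, dx, _, y0, _, dy = self.transform
        nrow, ncol = self.shape
        xs = sorted((x0, x0 + dx * ncol))
        ys = sorted((y0, y0 + dy * nrow))
        return xs[0], ys[0], xs[1], ys[1]

    def same_geometry(self, other: "Grid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and np.allclose(self.transform, other.transform, atol=atol)
        )

    # -- nodata handling ----------------------------------------------------

    @property
    def is_float(self) -> bool:
        return np.issubdtype(self.values.dtype, np.floating)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean array: True where the cell holds data."""
        if self.is_float:
            return np.isfinite(self.values) | np.isposinf(self.values)
        return self.values != self.nodata

    def masked(self) -> np.ndarray:
        """Float copy with nodata as NaN (works for int grids too)."""
        out = self.values.astype(float, copy=True)
        if not self.is_float:
            out[self.values == self.nodata] = np.nan
        return out

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """New grid with this geometry and the given values."""
        return Grid(
            values=values,
            transform=self.transform,
            crs=self.crs,
            nodata=self.nodata if nodata is None else nodata,
        )

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())


@dataclass
class AnnualStack:
    """Ordered sequence of grids on identical geometry, one per year."""

    years: list[int]
    layers: list[Grid] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.years = [int(y) for y in self.years]
        if len(self.years) != len(self.layers):
            raise ValueError("years and layers must have equal length")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if self.layers:
            ref = self.layers[0]
            for g in self.layers[1:]:
                if not g.same_geometry(ref):
                    raise ValueError("all stack layers must share geometry")

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self) -> Iterator[tuple[int, Grid]]:
        return iter(zip(self.years, self.layers))

    def __getitem__(self, year: int) -> Grid:
        try:
            return self.layers[self.years.index(int(year))]
        except ValueError:
            raise KeyError(f"year {year} not in stack") from None

    @property
    def geometry(self) -> Grid:
        if not self.layers:
            raise ValueError("empty stack has no geometry")
        return self.layers[0]

    def to_array(self) -> np.ndarray:
        """(n_years, nrow, ncol) float array with NaN nodata."""
        return np.stack([g.masked() for g in self.layers])

    @classmethod
    def from_array(
        cls, years: Sequence[int], arr: np.ndarray, template: Grid
    ) -> "AnnualStack":
        if arr.ndim != 3 or arr.shape[0] != len(years):
            raise ValueError("array must be (n_years, nrow, ncol)")
        return cls(
            years=list(years),
            layers=[template.like(arr[i].copy()) for i in range(arr.shape[0])],
        )

    def select(self, years: Sequence[int]) -> "AnnualStack":
        """Sub-stack restricted to the given years (must all be present)."""
        return AnnualStack(
            years=sorted(int(y) for y in years),
            layers=[self[y] for y in sorted(years)],
        )

    def map(self, func) -> "AnnualStack":
        return AnnualStack(years=list(self.years), layers=[func(g) for g in self.layers])
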