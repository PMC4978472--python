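"""Decadal temperature and altitude grids.

Grids are planar regular rasters. Internally row 0 is the *southernmost*
row and cells are addressed ``(row, col)``; a point maps to the half-open
cell ``[x0 + col*s, x0 + (col+1)*s)`` so behaviour at cell borders is
deterministic. ESRI ASCII files store rows north-first, so the reader and
writer flip row order.

Site-level temperatures follow the nine-cell rule: the mean of the 3x3
block of cells centred on the site's cell. The decadal "lowest air
temperature" around a site is the 1st percentile (linear interpolation
between order statistics) of the cell temperatures whose centres lie
within a lateral buffer of the site, 100 m by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CongruenceError, OutOfDomainError

logger = logging.getLogger(__name__)

GRID_KINDS = ("minimum", "maximum", "mean")

#: Default decadal warming offsets (degC relative to the 2000s baseline)
#: under the A1B emissions pathway.
A1B_OFFSETS: dict[str, float] = {
    "2000s": 0.0,
    "2020s": 0.5,
    "2040s": 1.2,
    "2060s": 2.4,
    "2080s": 3.5,
}


@dataclass(frozen=True)
class ClimateGrid:
    """Regular raster of air temperature (degC).

    Parameters
    ----------
    values
        2-D array, row 0 = southernmost row.
    cell_size
        Cell edge length in metres (> 0).
    origin
        ``(x, y)`` of the lower-left corner of the lower-left cell.
    decade_label
        Text label such as ``"2000s"``.
    kind
        One of ``"minimum"``, ``"maximum"``, ``"mean"``.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    decade_label: str = "2000s"
    kind: str = "mean"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("grid values must all be finite")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.kind not in GRID_KINDS:
            raise ValueError(f"kind must be one of {GRID_KINDS}")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of all cell centres (1-D each, matching axes)."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(nrows) + 0.5) * self.cell_size
        return xs, ys

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing a point."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y - y0) / self.cell_size))
        nrows, ncols = self.shape
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise OutOfDomainError(f"point ({x}, {y}) lies outside the grid")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        x0, y0 = self.origin
        nrows, ncols = self.shape
        return (x0 <= x < x0 + ncols * self.cell_size) and (
            y0 <= y < y0 + nrows * self.cell_size
        )


@dataclass(frozen=True)
class AltitudeGrid:
    """Altitude raster (m), congruent with any paired :class:`ClimateGrid`."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if np.any(vals < 0):
            raise ValueError("altitudes must be >= 0")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class WarmingScenario:
    """Ordered map decade label -> additive warming (degC) vs the baseline."""

    offsets: Mapping[str, float] = field(default_factory=lambda: dict(A1B_OFFSETS))

    def __post_init__(self):
        vals = list(self.offsets.values())
        if not vals:
            raise ValueError("scenario needs at least one decade")
        if vals[0] != 0.0:
            raise ValueError("baseline (first) offset must be 0")
        if np.any(np.diff(vals) < 0):
            raise ValueError("offsets must be non-decreasing over decades")

    @property
    def decades(self) -> list[str]:
        return list(self.offsets)

    def offset(self, decade: str) -> float:
        return self.offsets[decade]


def _check_congruent(a: ClimateGrid, b: ClimateGrid) -> None:
    if a.shape != b.shape or a.cell_size != b.cell_size or a.origin != b.origin:
        raise CongruenceError("grids differ in shape, cell size or origin")
    if a.decade_label != b.decade_label:
        raise CongruenceError(
            f"decade mismatch: {a.decade_label!r} vs {b.decade_label!r}"
        )


def decadal_mean_grid(min_grid: ClimateGrid, max_grid: ClimateGrid) -> ClimateGrid:
    """Cell-wise arithmetic average of decadal minimum and maximum grids."""
    _check_congruent(min_grid, max_grid)
    kinds = {min_grid.kind, max_grid.kind}
    if kinds != {"minimum", "maximum"} and min_grid.kind != max_grid.kind:
        raise CongruenceError("expected one minimum and one maximum grid")
    return replace(min_grid, values=(min_grid.values + max_grid.values) / 2.0, kind="mean")


def site_temperature(grid: ClimateGrid, site_xy: tuple[float, float]) -> float:
    """Nine-cell temperature at a site.

    Mean of the 3x3 block centred on the site's cell. Edge sites use the
    available (< 9) neighbours with a logged warning.
    """
    row, col = grid.cell_of(*site_xy)
    nrows, ncols = grid.shape
    r0, r1 = max(row - 1, 0), min(row + 2, nrows)
    c0, c1 = max(col - 1, 0), min(col + 2, ncols)
    block = grid.values[r0:r1, c0:c1]
    if block.size < 9:
        logger.warning(
            "site %s sits in an edge cell; nine-cell mean truncated to %d cells",
            site_xy, block.size,
        )
    return float(block.mean())


def site_temperatures(grid: ClimateGrid, xs: Iterable[float], ys: Iterable[float]) -> np.ndarray:
    """Vectorised :func:`site_temperature` over site coordinate sequences."""
    return np.array([site_temperature(grid, (x, y)) for x, y in zip(xs, ys)])


def apply_warming(baseline: ClimateGrid, scenario: WarmingScenario, decade: str) -> ClimateGrid:
    """Shift a baseline grid by a decade's warming offset."""
    if decade not in scenario.offsets:
        raise KeyError(f"decade {decade!r} not in scenario {scenario.decades}")
    return replace(
        baseline,
        values=baseline.values + scenario.offset(decade),
        decade_label=decade,
    )


def lowest_air_temperature(
    grid: ClimateGrid, site_xy: tuple[float, float], buffer_m: float = 100.0
) -> float:
    """1st percentile of cell temperatures within ``buffer_m`` of a site.

    Buffer membership is by Euclidean distance from the site to cell
    centres; the site's own cell is always included. Percentiles use
    linear interpolation between order statistics.
    """
    if buffer_m <= 0:
        raise ValueError("buffer_m must be > 0")
    x, y = site_xy
    if not grid.contains(x, y):
        raise OutOfDomainError(f"site ({x}, {y}) lies outside the grid")
    xs, ys = grid.cell_centres()
    dx = xs[None, :] - x
    dy = ys[:, None] - y
    mask = dx * dx + dy * dy <= buffer_m * buffer_m
    row, col = grid.cell_of(x, y)
    mask[row, col] = True
    vals = grid.values[mask]
    if vals.size == 0:  # pragma: no cover - own cell always present
        raise OutOfDomainError("buffer contains no cells")
    return float(np.percentile(vals, 1.0))


# ---------------------------------------------------------------------------
# Nine predictor surfaces
# ---------------------------------------------------------------------------

PREDICTOR_NAMES = (
    "annual_max", "annual_mean", "annual_min",
    "jan_max", "jan_mean", "jan_min",
    "jul_max", "jul_mean", "jul_min",
)


@dataclass(frozen=True)
class SeasonalClimate:
    """Annual-mean baseline plus a parametric seasonal decomposition.

    The nine predictor surfaces (annual / January / July, each with
    max / mean / min) are derived from the baseline annual-mean grid:
    January and July means are offset by ``winter_drop`` / ``summer_rise``
    modulated by smooth spatial anomaly fields, and per-month extremes sit
    ``half_range`` either side of the month mean. Annual extremes extend
    the same half range beyond the July/January means. Warming offsets
    shift all nine surfaces equally.
    """

    baseline: ClimateGrid
    winter_anomaly: np.ndarray
    summer_anomaly: np.ndarray
    winter_drop: float = 15.0
    summer_rise: float = 12.0
    half_range: float = 4.0

    def __post_init__(self):
        for anom in (self.winter_anomaly, self.summer_anomaly):
            if np.asarray(anom).shape != self.baseline.shape:
                raise CongruenceError("anomaly fields must match the baseline grid")

    def predictor_values(self, offset: float = 0.0) -> dict[str, np.ndarray]:
        """Per-cell values of the nine predictors at a warming offset."""
        v = self.baseline.values + offset
        jan = v - (self.winter_drop + self.winter_anomaly)
        jul = v + (self.summer_rise + self.summer_anomaly)
        h = self.half_range
        return {
            "annual_max": jul + h,
            "annual_mean": v,
            "annual_min": jan - h,
            "jan_max": jan + h,
            "jan_mean": jan,
            "jan_min": jan - h,
            "jul_max": jul + h,
            "jul_mean": jul,
            "jul_min": jul - h,
        }

    def predictor_grids(self, decade: str, scenario: WarmingScenario) -> dict[str, ClimateGrid]:
        vals = self.predictor_values(scenario.offset(decade))
        return {
            name: replace(self.baseline, values=arr, decade_label=decade)
            for name, arr in vals.items()
        }

    def site_predictors(
        self, xs: Iterable[float], ys: Iterable[float], offset: float = 0.0
    ) -> pd.DataFrame:
        """Nine-cell site means of each predictor surface (one row per site)."""
        grids = self.predictor_values(offset)
        out = {}
        for name in PREDICTOR_NAMES:
            g = replace(self.baseline, values=grids[name])
            out[name] = site_temperatures(g, xs, ys)
        return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and long-format CSV
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_asc(grid: ClimateGrid | AltitudeGrid, path: str | Path) -> None:
    """Write a grid as ESRI ASCII (.asc). Rows are stored north-first."""
    nrows, ncols = grid.shape
    x0, y0 = grid.origin
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner {x0}\nyllcorner {y0}\n"
        f"cellsize {grid.cell_size}\nNODATA_value {_NODATA}\n"
    )
    body = np.flipud(grid.values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_asc(
    path: str | Path, decade_label: str = "2000s", kind: str = "mean"
) -> ClimateGrid:
    """Read an ESRI ASCII grid into a :class:`ClimateGrid`."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", _NODATA)
    if np.any(values == nodata):
        raise ValueError("NODATA cells are not supported")
    return ClimateGrid(
        values=np.flipud(values),
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        decade_label=decade_label,
        kind=kind,
    )


def grid_to_frame(grid: ClimateGrid | AltitudeGrid) -> pd.DataFrame:
    """Long-format (row, col, x, y, value) table of a grid."""
    nrows, ncols = grid.shape
    rows, cols = np.mgrid[0:nrows, 0:ncols]
    x0, y0 = grid.origin
    return pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "x": x0 + (cols.ravel() + 0.5) * grid.cell_size,
            "y": y0 + (rows.ravel() + 0.5) * grid.cell_size,
            "value": grid.values.ravel(),
        }
    )
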