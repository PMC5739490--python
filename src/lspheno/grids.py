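"""Gridded data model: grid specification, raster cubes, land-cover maps.

All grids are regular lon/lat grids. Row 0 is the northernmost row and
coordinates refer to cell centers. Missing values are IEEE NaN in memory.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CADENCES = ("composite-15d", "daily", "monthly", "annual")

#: Midpoint day-of-year of the 24 fifteen-day compositing windows.
#: Window k covers days [15k+1, 15k+15]; the last window absorbs days 361-365.
COMPOSITE_DOYS = np.arange(8, 8 + 15 * 24, 15)  # 8, 23, ..., 353
N_COMPOSITES = 24


_MONTH_END_DOY = np.array([31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334, 365])


def month_of_day(doy: float) -> int:
    """Calendar month (1-12) containing a (non-leap) 1-based day of year."""
    return int(np.searchsorted(_MONTH_END_DOY, doy) + 1)


def composite_windows() -> np.ndarray:
    """(24, 2) inclusive day-of-year bounds of each compositing window."""
    starts = np.arange(0, 24) * 15 + 1
    ends = starts + 14
    ends[-1] = 365  # days 361-365 absorbed into the last window
    return np.column_stack([starts, ends])


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid.

    ``origin`` is the (lon, lat) of the *upper-left corner* of the grid,
    i.e. the north-west corner of cell (0, 0).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    id: str = ""

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, row 0 northernmost."""
        lon0, lat0 = self.origin
        return lat0 - self.cell_size * (np.arange(self.n_rows) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        lon0, lat0 = self.origin
        return lon0 + self.cell_size * (np.arange(self.n_cols) + 0.5)

    def coarsen(self, factor: int, id: str = "") -> "GridSpec":
        """Grid with ``factor``-times larger cells covering the same extent."""
        if factor < 1 or self.n_rows % factor or self.n_cols % factor:
            raise ValueError(
                f"grid {self.n_rows}x{self.n_cols} does not divide by factor {factor}"
            )
        return GridSpec(
            self.n_rows // factor,
            self.n_cols // factor,
            self.cell_size * factor,
            self.origin,
            id or f"{self.id}/coarse{factor}",
        )

    def nesting_factor(self, target: "GridSpec") -> int:
        """Integer number of this grid's cells per ``target`` cell, or raise."""
        ratio = target.cell_size / self.cell_size
        factor = int(round(ratio))
        if (
            factor < 1
            or abs(ratio - factor) > 1e-6
            or self.n_rows != target.n_rows * factor
            or self.n_cols != target.n_cols * factor
            or np.max(np.abs(np.subtract(self.origin, target.origin))) > 1e-6
        ):
            raise ValueError(f"grids do not nest: {self} vs {target}")
        return factor


@dataclass
class RasterCube:
    """A (time, row, col) gridded variable with calendar timestamps.

    ``times`` are numpy datetime64[D]; they must be strictly increasing.
    NDVI cubes are validated to lie in [-1, 1] (or NaN).
    """

    values: np.ndarray
    times: np.ndarray
    cadence: str
    grid: GridSpec
    variable: str
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype="datetime64[D]")
        if self.cadence not in CADENCES:
            raise ValueError(f"unknown cadence {self.cadence!r}")
        if self.values.ndim != 3:
            raise ValueError("values must be a (time, row, col) array")
        if self.values.shape != (len(self.times), self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.times)} timestamps and grid {self.grid.shape}"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times).astype(int) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.variable.lower() == "ndvi":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1 or finite.max() > 1):
                raise ValueError(
                    "NDVI outside [-1, 1]: "
                    f"range [{finite.min():.4f}, {finite.max():.4f}]"
                )

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def years(self) -> np.ndarray:
        """Calendar year of each time step."""
        return pd.DatetimeIndex(self.times).year.to_numpy()

    @property
    def doys(self) -> np.ndarray:
        """1-based day-of-year of each time step."""
        return pd.DatetimeIndex(self.times).dayofyear.to_numpy()

    @property
    def months(self) -> np.ndarray:
        return pd.DatetimeIndex(self.times).month.to_numpy()

    def copy(self) -> "RasterCube":
        return RasterCube(
            self.values.copy(), self.times.copy(), self.cadence,
            self.grid, self.variable, self.units,
        )


# --- land cover ---------------------------------------------------------

#: MODIS IGBP 17-class legend (code -> name).
IGBP17 = {
    1: "evergreen_needleleaf_forest",
    2: "evergreen_broadleaf_forest",
    3: "deciduous_needleleaf_forest",
    4: "deciduous_broadleaf_forest",
    5: "mixed_forest",
    6: "closed_shrubland",
    7: "open_shrubland",
    8: "woody_savanna",
    9: "savanna",
    10: "grassland",
    11: "permanent_wetland",
    12: "cropland",
    13: "urban",
    14: "cropland_mosaic",
    15: "snow_ice",
    16: "barren",
    17: "water",
}

#: Grouped legend used for stratified summaries.
GROUPED4 = {1: "grassland", 2: "shrubland", 3: "forest", 4: "other"}
GRASSLAND, SHRUBLAND, FOREST, OTHER = 1, 2, 3, 4

SCHEMES = {"IGBP-17": set(IGBP17), "grouped-4": set(GROUPED4)}


@dataclass
class LandCoverMap:
    """Per-pixel categorical land cover on a grid."""

    codes: np.ndarray
    grid: GridSpec
    scheme: str = "IGBP-17"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.shape != self.grid.shape:
            raise ValueError("codes shape inconsistent with grid")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        bad = sorted(set(self.codes.ravel()) - SCHEMES[self.scheme])
        if bad:
            raise ValueError(f"codes {bad} not in scheme {self.scheme}")

    def class_names(self) -> dict[int, str]:
        return IGBP17 if self.scheme == "IGBP-17" else GROUPED4
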