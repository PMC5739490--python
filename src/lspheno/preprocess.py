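"""Data cleaning: snow-contamination handling and vegetation masking.

Winter NDVI composites can be corrupted by snow cover. A composite is
treated as potentially snow-covered when its 15-day window overlaps a run
of at least five consecutive days with daily mean temperature strictly
below 0 °C at that pixel; such composites are replaced by the same pixel's
NDVI at the temporally nearest snow-free composite (ties toward the
earlier one). Pixels without a visible seasonal cycle — mean NDVI over
the whole record below 0.1 — are excluded from phenology extraction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import RasterCube

logger = logging.getLogger(__name__)

MIN_FROST_RUN = 5  # consecutive sub-zero days that define a frost run
VEGETATION_NDVI_MIN = 0.1


@dataclass
class SnowMask:
    """Boolean flags aligned to an NDVI cube's composites (time, row, col)."""

    flags: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.times = np.asarray(self.times, dtype="datetime64[D]")
        if self.flags.shape[0] != len(self.times):
            raise ValueError("flags and times length mismatch")


@dataclass
class VegetationMask:
    """Per-pixel validity (row, col): True where a seasonal cycle exists."""

    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)


def _frost_run_days(frozen: np.ndarray, min_run: int = MIN_FROST_RUN) -> np.ndarray:
    """Days that belong to a run of >= min_run consecutive frozen days.

    ``frozen`` is boolean (time, row, col); two linear passes over time,
    vectorised over pixels.
    """
    n = frozen.shape[0]
    runlen = np.zeros(frozen.shape, dtype=np.int32)
    runlen[0] = frozen[0]
    for t in range(1, n):
        runlen[t] = (runlen[t - 1] + 1) * frozen[t]
    total = runlen.copy()  # max run length over each run, propagated backward
    for t in range(n - 2, -1, -1):
        total[t] = np.where(
            frozen[t] & frozen[t + 1], np.maximum(total[t], total[t + 1]), total[t]
        )
    return total >= min_run


def _composite_window_dates(time: np.datetime64) -> tuple[np.datetime64, np.datetime64]:
    """Inclusive date bounds of the 15-day window a composite midpoint sits in."""
    ts = pd.Timestamp(time)
    k = min((ts.dayofyear - 1) // 15, 23)
    start = np.datetime64(f"{ts.year}-01-01") + np.timedelta64(15 * k, "D")
    if k == 23:  # last window absorbs the trailing days of the year
        end = np.datetime64(f"{ts.year}-12-31")
    else:
        end = start + np.timedelta64(14, "D")
    return start, end


def detect_snow(daily_temp: RasterCube, composite_times: np.ndarray) -> SnowMask:
    """Flag composites whose window overlaps a >=5-day sub-zero frost run.

    ``daily_temp`` must cover every composite window; a coverage gap raises
    naming the window.
    """
    if daily_temp.cadence != "daily":
        raise ValueError("detect_snow needs a daily temperature cube")
    composite_times = np.asarray(composite_times, dtype="datetime64[D]")
    in_run = _frost_run_days(daily_temp.values < 0.0)
    days = daily_temp.times
    flags = np.zeros((len(composite_times),) + daily_temp.grid.shape, dtype=bool)
    for i, t in enumerate(composite_times):
        start, end = _composite_window_dates(t)
        if start < days[0] or end > days[-1]:
            raise ValueError(
                f"daily temperature does not cover composite window {start}..{end}"
            )
        i0 = int(np.searchsorted(days, start))
        i1 = int(np.searchsorted(days, end, side="right"))
        flags[i] = in_run[i0:i1].any(axis=0)
    return SnowMask(flags, composite_times)


def replace_snow(ndvi: RasterCube, mask: SnowMask) -> RasterCube:
    """Replace flagged composites by the nearest snow-free composite value.

    Replacement is per pixel and temporal: each flagged composite takes the
    same pixel's NDVI at the nearest unflagged time index, ties toward the
    earlier composite. Unflagged values are returned bit-identical. A pixel
    with every composite flagged raises, listing the pixel.
    """
    if mask.flags.shape != ndvi.values.shape:
        raise ValueError("snow mask not aligned to NDVI cube")
    out = ndvi.copy()
    vals = out.values
    flags = mask.flags
    n_rows, n_cols = ndvi.grid.shape
    all_flagged = []
    for r in range(n_rows):
        for c in range(n_cols):
            f = flags[:, r, c]
            if not f.any():
                continue
            free = np.flatnonzero(~f)
            if free.size == 0:
                all_flagged.append((r, c))
                continue
            hit = np.flatnonzero(f)
            pos = np.searchsorted(free, hit)
            left = free[np.clip(pos - 1, 0, free.size - 1)]
            right = free[np.clip(pos, 0, free.size - 1)]
            d_left = np.where(pos > 0, hit - left, np.iinfo(np.int64).max)
            d_right = np.where(pos < free.size, right - hit, np.iinfo(np.int64).max)
            src = np.where(d_left <= d_right, left, right)  # tie -> earlier
            vals[hit, r, c] = vals[src, r, c]
    if all_flagged:
        raise ValueError(
            f"pixels with all composites snow-flagged: {all_flagged[:10]}"
            + ("..." if len(all_flagged) > 10 else "")
        )
    return out


def vegetation_mask(ndvi: RasterCube) -> VegetationMask:
    """Pixels with mean NDVI (all composites, all years) >= 0.1 are valid.

    Strictly-below-0.1 pixels lack a usable seasonal cycle and are
    excluded; all-missing pixels are invalid (count logged).
    """
    if ndvi.n_times < 24:
        raise ValueError("need at least one full year of composites")
    finite = np.isfinite(ndvi.values)
    n_ok = finite.sum(axis=0)
    mean = np.where(finite, ndvi.values, 0.0).sum(axis=0) / np.where(n_ok > 0, n_ok, 1)
    all_missing = n_ok == 0
    if all_missing.any():
        logger.info("vegetation_mask: %d all-missing pixels", int(all_missing.sum()))
    valid = np.where(all_missing, False, mean >= VEGETATION_NDVI_MIN)
    return VegetationMask(valid)
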