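"""Preseason climate attribution of phenological variation.

Per 0.5-degree-style coarse cell, yearly SOS/EOS series (means of the
fine-grid phenology pixels) are related to preseason climate. The
preseason of an event is the window of 0-5 calendar months ending in the
month of the cell's long-term mean event date; temperature is averaged
over the window, precipitation and insolation are summed. For each
climate variable the preseason length maximising the absolute Pearson
correlation with the event series is selected (ties toward the shorter
window), and the partial correlation of the event with that variable --
controlling for the other two climate variables at their own selected
lags -- is computed from the inverse of the joint correlation matrix.
An additional EOS-vs-SOS partial correlation controls for the three
EOS-preseason climate variables.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import GROUPED4, GridSpec, LandCoverMap, RasterCube
from .phenology import Flag, PhenologySeries
from .grids import month_of_day as _month_of_day
from .trends import TrendResult, pixel_trend

CLIMATE_VARS = ("temperature", "precipitation", "insolation")
#: Aggregation over the preseason window, per variable.
AGGREGATION = {"temperature": "mean", "precipitation": "sum", "insolation": "sum"}
MAX_LAG = 5
MIN_YEARS = 10


@dataclass(frozen=True)
class PreseasonSpec:
    event: str  # 'sos' | 'eos'
    variable: str
    lag: int  # months before the event month, 0..5
    aggregation: str

    def __post_init__(self) -> None:
        if not 0 <= self.lag <= MAX_LAG:
            raise ValueError("lag must be 0..5 months")
        if AGGREGATION.get(self.variable, self.aggregation) != self.aggregation:
            raise ValueError(
                f"{self.variable} must be aggregated by {AGGREGATION[self.variable]}"
            )


def aggregate_phenology(
    pheno: PhenologySeries, target: GridSpec, min_valid_frac: float = 0.5
) -> dict[str, np.ndarray]:
    """Average fine-grid SOS/EOS dates into coarse cells, per year.

    A cell-year is missing when fewer than ``min_valid_frac`` of the
    covered fine pixels have an OK date that year.
    """
    factor = pheno.grid.nesting_factor(target)
    ok = pheno.flags == Flag.OK
    out: dict[str, np.ndarray] = {}
    n_years = len(pheno.years)
    for metric in ("sos", "eos"):
        vals = np.where(ok, getattr(pheno, metric), np.nan)
        blocks = vals.reshape(n_years, target.n_rows, factor, target.n_cols, factor)
        flat = blocks.transpose(0, 1, 3, 2, 4).reshape(
            n_years, target.n_rows, target.n_cols, factor * factor
        )
        finite = np.isfinite(flat)
        n_ok = finite.sum(axis=-1)
        with np.errstate(invalid="ignore"):
            mean = np.where(finite, flat, 0.0).sum(axis=-1) / np.where(
                n_ok > 0, n_ok, 1
            )
        mean[n_ok < min_valid_frac * factor * factor] = np.nan
        mean[n_ok == 0] = np.nan
        out[metric] = mean
    out["years"] = pheno.years
    return out


def _monthly_matrix(cube: RasterCube) -> tuple[np.ndarray, np.ndarray]:
    """(n_years*12, rows, cols) matrix of a monthly cube + its years."""
    if cube.cadence != "monthly":
        raise ValueError("need a monthly climate cube")
    years = cube.years
    uyears = np.unique(years)
    if len(cube.times) != 12 * len(uyears):
        raise ValueError("monthly cube must cover whole years")
    return cube.values, uyears


def preseason_series(
    climate: RasterCube,
    event_month: np.ndarray,
    lag: int,
    variable: str | None = None,
) -> np.ndarray:
    """Per-cell yearly preseason aggregates of one climate variable.

    ``event_month`` is a (rows, cols) integer array of the long-term mean
    event month per cell (1-12, fixed across years). The window spans
    months [event_month - lag, event_month] of each year; windows that
    would start before the record begin yield NaN for that year.
    """
    variable = variable or climate.variable
    how = AGGREGATION[variable]
    vals, uyears = _monthly_matrix(climate)
    n_years = len(uyears)
    shape = climate.grid.shape
    event_month = np.asarray(event_month)
    if event_month.shape != shape:
        raise ValueError("event_month not on the climate grid")
    out = np.full((n_years,) + shape, np.nan)
    for m in np.unique(event_month[np.isfinite(event_month.astype(float))]):
        m = int(m)
        sel = event_month == m
        for yi in range(n_years):
            end = yi * 12 + m - 1
            start = end - lag
            if start < 0:
                continue
            win = vals[start : end + 1][:, sel]
            out[yi, sel] = win.mean(axis=0) if how == "mean" else win.sum(axis=0)
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < 3:
        return np.nan, n
    xs, ys = x[keep], y[keep]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan, n
    return float(np.corrcoef(xs, ys)[0, 1]), n


def select_lag(
    event_series: np.ndarray,
    lag_series: dict[int, np.ndarray],
    min_years: int = MIN_YEARS,
) -> tuple[int, float] | None:
    """Preseason length with the highest absolute Pearson correlation.

    Ties go to the shorter preseason. Returns None when no lag has a
    defined correlation over at least ``min_years`` overlapping years.
    """
    best: tuple[int, float] | None = None
    for lag in sorted(lag_series):
        r, n = _pearson(event_series, lag_series[lag])
        if not np.isfinite(r) or n < min_years:
            continue
        if best is None or abs(r) > abs(best[1]):
            best = (lag, r)
    return best


def partial_correlation(
    x: np.ndarray, y: np.ndarray, controls: tuple[np.ndarray, ...] = ()
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given control series.

    Computed from the inverse of the joint correlation matrix over
    complete years; the p-value is two-sided from
    t = r * sqrt((n - 2 - k) / (1 - r^2)) with k controls. Returns
    (r, p, n); (NaN, NaN, n) when fewer than k + 3 complete years remain
    or the correlation matrix is singular (e.g. a constant series).
    """
    cols = [np.asarray(x, dtype=float), np.asarray(y, dtype=float)] + [
        np.asarray(c, dtype=float) for c in controls
    ]
    data = np.column_stack(cols)
    keep = np.all(np.isfinite(data), axis=1)
    data = data[keep]
    n, k = data.shape[0], len(controls)
    if n < k + 3:
        return np.nan, np.nan, n
    if np.any(data.std(axis=0) == 0):
        return np.nan, np.nan, n
    corr = np.corrcoef(data, rowvar=False)
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, n
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        return np.nan, np.nan, n
    r = float(np.clip(-prec[0, 1] / np.sqrt(denom), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, n


def _event_month_map(series: np.ndarray) -> np.ndarray:
    """Calendar month of the long-term mean event date, per cell (0 = missing)."""
    finite = np.isfinite(series)
    n_ok = finite.sum(axis=0)
    mean_day = np.where(finite, series, 0.0).sum(axis=0) / np.where(n_ok > 0, n_ok, 1)
    out = np.zeros(mean_day.shape, dtype=np.int64)
    ok = n_ok > 0
    for idx in zip(*np.nonzero(ok)):
        out[idx] = _month_of_day(float(np.clip(mean_day[idx], 1, 365)))
    return out


def attribute(
    pheno_cells: dict[str, np.ndarray],
    climate: dict[str, RasterCube],
    lags: range = range(MAX_LAG + 1),
    min_years: int = MIN_YEARS,
) -> pd.DataFrame:
    """Per-cell partial-correlation attribution of SOS and EOS.

    ``pheno_cells`` is the output of :func:`aggregate_phenology`;
    ``climate`` maps variable name to its monthly cube on the same coarse
    grid. For each cell and event, the preseason lag of each climate
    variable is selected by plain correlation, then the partial
    correlation of the event with that variable is computed controlling
    for the other two climate variables at their own selected lags. For
    EOS an additional row relates EOS to SOS controlling for the three
    EOS-preseason climate variables.
    """
    years = pheno_cells["years"]
    grid_shape = pheno_cells["sos"].shape[1:]
    for var in CLIMATE_VARS:
        if var not in climate:
            raise ValueError(f"missing climate cube {var!r}")
        if climate[var].grid.shape != grid_shape:
            raise ValueError(f"{var} cube not on the phenology cell grid")
    cyears = np.unique(climate["temperature"].years)
    if not np.array_equal(cyears, years):
        raise ValueError("climate and phenology year ranges differ")

    # preseason aggregates per event, variable and lag: (n_years, rows, cols)
    aggs: dict[tuple[str, str, int], np.ndarray] = {}
    months: dict[str, np.ndarray] = {}
    for event in ("sos", "eos"):
        months[event] = _event_month_map(pheno_cells[event])
        for var in CLIMATE_VARS:
            for lag in lags:
                aggs[(event, var, lag)] = preseason_series(
                    climate[var], months[event], lag, var
                )

    rows = []
    for r in range(grid_shape[0]):
        for c in range(grid_shape[1]):
            if months["sos"][r, c] == 0 or months["eos"][r, c] == 0:
                continue
            chosen: dict[tuple[str, str], np.ndarray] = {}
            lag_of: dict[tuple[str, str], int] = {}
            for event in ("sos", "eos"):
                ev = pheno_cells[event][:, r, c]
                for var in CLIMATE_VARS:
                    series_by_lag = {
                        lag: aggs[(event, var, lag)][:, r, c] for lag in lags
                    }
                    pick = select_lag(ev, series_by_lag, min_years)
                    if pick is None:
                        continue
                    lag_of[(event, var)] = pick[0]
                    chosen[(event, var)] = series_by_lag[pick[0]]
                for var in CLIMATE_VARS:
                    if (event, var) not in chosen:
                        rows.append(
                            dict(row=r, col=c, event=event, variable=var,
                                 lag=np.nan, partial_r=np.nan, p_value=np.nan,
                                 n_years=0)
                        )
                        continue
                    controls = tuple(
                        chosen[(event, v)]
                        for v in CLIMATE_VARS
                        if v != var and (event, v) in chosen
                    )
                    pr, p, n = partial_correlation(ev, chosen[(event, var)], controls)
                    rows.append(
                        dict(row=r, col=c, event=event, variable=var,
                             lag=lag_of[(event, var)], partial_r=pr,
                             p_value=p, n_years=n)
                    )
            # EOS vs SOS, controlling the EOS-preseason climate
            eos_controls = tuple(
                chosen[("eos", v)] for v in CLIMATE_VARS if ("eos", v) in chosen
            )
            pr, p, n = partial_correlation(
                pheno_cells["eos"][:, r, c], pheno_cells["sos"][:, r, c], eos_controls
            )
            rows.append(
                dict(row=r, col=c, event="eos", variable="sos", lag=np.nan,
                     partial_r=pr, p_value=p, n_years=n)
            )
    return pd.DataFrame(rows)


def summarize_attribution(
    results: pd.DataFrame,
    landcover: LandCoverMap,
    alpha: float = 0.05,
    min_years: int = MIN_YEARS,
) -> pd.DataFrame:
    """Percent of cells with significant positive/negative partial r,
    per event x land-cover class x variable.

    Cells with fewer than ``min_years`` complete years are excluded;
    empty classes are emitted with zero counts.
    """
    if landcover.scheme != "grouped-4":
        raise ValueError("summaries need a grouped-4 land-cover map")
    rows = []
    variables = [v for v in results["variable"].unique()]
    for event in ("sos", "eos"):
        for code, name in GROUPED4.items():
            for var in variables:
                sub = results[
                    (results["event"] == event)
                    & (results["variable"] == var)
                    & (results["n_years"] >= min_years)
                ]
                if len(sub):
                    in_class = landcover.codes[
                        sub["row"].to_numpy(), sub["col"].to_numpy()
                    ] == code
                    sub = sub[in_class & np.isfinite(sub["partial_r"])]
                n = len(sub)
                sig = sub[sub["p_value"] < alpha] if n else sub
                pos = int((sig["partial_r"] > 0).sum()) if n else 0
                neg = int((sig["partial_r"] < 0).sum()) if n else 0
                rows.append(
                    {
                        "event": event,
                        "class": name,
                        "variable": var,
                        "pct_positive": 100.0 * pos / n if n else 0.0,
                        "pct_negative": 100.0 * neg / n if n else 0.0,
                        "n_cells": n,
                    }
                )
    return pd.DataFrame(rows)


def climate_trend(series: np.ndarray, years: np.ndarray) -> TrendResult | None:
    """Linear trend of a preseason climate aggregate (delegates to the
    pixel-trend OLS)."""
    return pixel_trend(years, series, metric="climate")
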