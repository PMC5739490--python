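"""Polyfit-Mr phenology extraction.

The method dates the growing season in three steps, per pixel:

1. fit a six-degree polynomial to the multi-year mean (climatology) of the
   15-day NDVI composites, interpolating the seasonal cycle to daily
   resolution;
2. define the start (SOS) and end (EOS) of the season as the days where
   the fitted daily curve changes fastest — the maximum and minimum of its
   first derivative — and record the fitted NDVI values at those days as
   per-pixel thresholds;
3. for each individual year, fit the year's own polynomial and date SOS as
   the first upward crossing of the SOS threshold before the annual
   maximum, EOS as the last downward crossing of the EOS threshold after
   it. Growing-season length (GSL) is EOS minus SOS.

The polynomial coefficients are solved by linear least squares and then
refined with the Levenberg-Marquardt algorithm (which, the model being
linear in its coefficients, converges immediately to the same optimum —
kept for fidelity to the published procedure, with the linear solution as
the built-in cross-check). Days are normalised to t = day/365 for
conditioning; all day-of-year values are 1-based.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy.optimize import least_squares

from .grids import GridSpec, RasterCube
from .preprocess import SnowMask, VegetationMask

DEGREE = 6
_DAYS = np.arange(1, 366)
_T = _DAYS / 365.0


class FitError(ValueError):
    """Polynomial fit impossible or no coherent seasonal cycle."""


class Flag(IntEnum):
    OK = 0
    NO_SOS_CROSSING = 1
    NO_EOS_CROSSING = 2
    FIT_FAILED = 3
    MASKED = 4


@dataclass
class PolynomialFit:
    coeffs: np.ndarray  # ascending powers of t = day/365, length 7
    rmse: float
    n_points: int

    def __call__(self, days: np.ndarray) -> np.ndarray:
        return P.polyval(np.asarray(days, dtype=float) / 365.0, self.coeffs)

    def derivative(self, days: np.ndarray) -> np.ndarray:
        """dNDVI/dday of the fitted curve (chain rule for t = day/365)."""
        dc = P.polyder(self.coeffs)
        return P.polyval(np.asarray(days, dtype=float) / 365.0, dc) / 365.0


@dataclass
class PhenoThresholds:
    sos_day_clim: int  # day of maximum NDVI rate of change
    eos_day_clim: int  # day of minimum rate of change
    sos_ndvi: float
    eos_ndvi: float


def fit_polynomial(
    values: np.ndarray, days: np.ndarray, refine: bool = True
) -> PolynomialFit:
    """Degree-6 least-squares fit on t = day/365, with L-M refinement.

    Requires at least 7 finite points. ``refine=False`` skips the
    Levenberg-Marquardt step and returns the plain linear solution.
    """
    values = np.asarray(values, dtype=float)
    days = np.asarray(days, dtype=float)
    keep = np.isfinite(values) & np.isfinite(days)
    values, days = values[keep], days[keep]
    if values.size < DEGREE + 1:
        raise FitError(f"need >= {DEGREE + 1} finite points, got {values.size}")
    t = days / 365.0
    V = P.polyvander(t, DEGREE)
    c0, *_ = np.linalg.lstsq(V, values, rcond=None)
    c = c0
    if refine:
        sol = least_squares(
            lambda coef: V @ coef - values,
            x0=c0,
            jac=lambda coef: V,
            method="lm",
            gtol=1e-8,
            max_nfev=1000,
        )
        c = sol.x
    resid = V @ c - values
    return PolynomialFit(c, float(np.sqrt(np.mean(resid**2))), int(values.size))


def climatology(
    year_matrix: np.ndarray,
) -> np.ndarray:
    """Mean seasonal cycle over years, ignoring missing values.

    ``year_matrix`` is (n_years, n_composites); raises when a composite
    index is missing in every year.
    """
    year_matrix = np.asarray(year_matrix, dtype=float)
    if year_matrix.ndim != 2 or year_matrix.shape[0] < 2:
        raise ValueError("need a (years >= 2, composites) matrix")
    counts = np.isfinite(year_matrix).sum(axis=0)
    if np.any(counts == 0):
        missing = np.flatnonzero(counts == 0).tolist()
        raise FitError(f"composite indices missing in all years: {missing}")
    with np.errstate(invalid="ignore"):
        return np.nanmean(year_matrix, axis=0)


def _interior_extremum(values: np.ndarray, kind: str) -> int:
    """Index of the best *interior local* max/min, else the global one.

    A degree-6 polynomial fitted to a seasonal cycle with flat winter
    tails can swing steeply at the year boundaries; the greenup and
    senescence extrema of the derivative are interior local extrema, so
    boundary artifacts are ignored whenever an interior candidate exists.
    """
    v = values if kind == "max" else -values
    local = np.flatnonzero((v[1:-1] >= v[:-2]) & (v[1:-1] >= v[2:])) + 1
    if local.size == 0:
        return int(np.argmax(v))
    return int(local[np.argmax(v[local])])


def derive_thresholds(fit: PolynomialFit) -> PhenoThresholds:
    """SOS/EOS climatological dates and NDVI thresholds from the fitted curve.

    The first derivative is evaluated analytically on days 1..365; the
    greenup (SOS) date is its maximum and the senescence (EOS) date its
    minimum, taken over interior local extrema to discount polynomial
    edge effects. A curve whose maximum rate of change does not precede
    its minimum has no coherent seasonal cycle and raises
    :class:`FitError`.
    """
    d1 = fit.derivative(_DAYS)
    sos_day = int(_DAYS[_interior_extremum(d1, "max")])
    eos_day = int(_DAYS[_interior_extremum(d1, "min")])
    if sos_day >= eos_day:
        raise FitError(
            f"no coherent seasonal cycle (greenup day {sos_day} >= "
            f"senescence day {eos_day})"
        )
    curve = fit(_DAYS)
    return PhenoThresholds(
        sos_day, eos_day, float(curve[sos_day - 1]), float(curve[eos_day - 1])
    )


def date_year(
    year_values: np.ndarray,
    days: np.ndarray,
    thresholds: PhenoThresholds,
    year_smoother: str = "interp",
    refine: bool = True,
) -> tuple[float, float, Flag]:
    """Date SOS and EOS for one year against climatological thresholds.

    The year's composites are interpolated to a daily curve, then SOS is
    dated as the first upward crossing of the SOS threshold in [day 1,
    day of the annual maximum] and EOS as the first downward crossing of
    the EOS threshold in [annual maximum, day 365], linearly interpolated
    between integer days to sub-day resolution. Taking the *first*
    downward crossing after the seasonal peak (rather than the last of
    the year) keeps spurious re-crossings out of the EOS date.

    ``year_smoother`` selects the daily curve: ``"interp"`` (default)
    interpolates the composites linearly — a local scheme, so a change in
    one season cannot perturb the dated crossing in the other;
    ``"polynomial"`` refits the year's own degree-6 curve (the global
    basis couples the two seasons slightly, which attenuates opposing
    SOS/EOS trends; kept as an option for comparison).

    Returns (sos, eos, flag); a missing crossing yields NaN for that date
    and the corresponding flag.
    """
    year_values = np.asarray(year_values, dtype=float)
    days = np.asarray(days, dtype=float)
    keep = np.isfinite(year_values) & np.isfinite(days)
    if keep.sum() < DEGREE + 1:
        return np.nan, np.nan, Flag.FIT_FAILED
    if year_smoother == "polynomial":
        try:
            fit = fit_polynomial(year_values, days, refine=refine)
        except FitError:
            return np.nan, np.nan, Flag.FIT_FAILED
        curve = fit(_DAYS)
    elif year_smoother == "interp":
        curve = np.interp(_DAYS, days[keep], year_values[keep])
    else:
        raise ValueError(f"unknown year_smoother {year_smoother!r}")
    imax = _interior_extremum(curve, "max")

    sos = np.nan
    seg = curve[: imax + 1]
    ups = np.flatnonzero((seg[:-1] < thresholds.sos_ndvi) & (seg[1:] >= thresholds.sos_ndvi))
    if ups.size:
        i = int(ups[0])
        frac = (thresholds.sos_ndvi - seg[i]) / (seg[i + 1] - seg[i])
        sos = float(_DAYS[i] + frac)

    eos = np.nan
    seg = curve[imax:]
    downs = np.flatnonzero((seg[:-1] >= thresholds.eos_ndvi) & (seg[1:] < thresholds.eos_ndvi))
    if downs.size:
        i = int(downs[0])
        frac = (seg[i] - thresholds.eos_ndvi) / (seg[i] - seg[i + 1])
        eos = float(_DAYS[imax + i] + frac)

    if np.isnan(sos):
        return sos, eos, Flag.NO_SOS_CROSSING
    if np.isnan(eos):
        return sos, eos, Flag.NO_EOS_CROSSING
    return sos, eos, Flag.OK


@dataclass
class PhenologySeries:
    """Per pixel x year SOS/EOS (day-of-year), GSL (days) and quality flags.

    ``sos``/``eos``/``gsl`` are (n_years, rows, cols) floats with NaN for
    missing; ``flags`` is int8 with :class:`Flag` codes. When a snow mask
    was supplied, dates clamped to the thermal growing season are recorded
    in ``sos_clamped``/``eos_clamped`` (the flag stays OK).
    """

    years: np.ndarray
    sos: np.ndarray
    eos: np.ndarray
    gsl: np.ndarray
    flags: np.ndarray
    grid: GridSpec
    sos_clamped: np.ndarray | None = None
    eos_clamped: np.ndarray | None = None

    def ok(self) -> np.ndarray:
        return self.flags == Flag.OK

    def to_dataframe(self) -> pd.DataFrame:
        n_years, n_rows, n_cols = self.sos.shape
        yy, rr, cc = np.meshgrid(
            self.years, np.arange(n_rows), np.arange(n_cols), indexing="ij"
        )
        return pd.DataFrame(
            {
                "year": yy.ravel(),
                "row": rr.ravel(),
                "col": cc.ravel(),
                "sos": self.sos.ravel(),
                "eos": self.eos.ravel(),
                "gsl": self.gsl.ravel(),
                "flag": [Flag(f).name.lower() for f in self.flags.ravel()],
            }
        )


def _year_matrix(ndvi: RasterCube) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reshape a composite cube to (years, 24, rows, cols) + composite doys."""
    years = ndvi.years
    uyears = np.unique(years)
    doys = ndvi.doys
    k = np.minimum((doys - 1) // 15, 23)
    n_rows, n_cols = ndvi.grid.shape
    out = np.full((len(uyears), 24, n_rows, n_cols), np.nan)
    yi = np.searchsorted(uyears, years)
    out[yi, k] = ndvi.values
    mid_days = np.arange(8, 8 + 15 * 24, 15).astype(float)
    return out, uyears, mid_days


def extract_phenology(
    ndvi: RasterCube,
    mask: VegetationMask | None = None,
    snow_mask: SnowMask | None = None,
    year_smoother: str = "interp",
    refine: bool = True,
) -> PhenologySeries:
    """Run the full Polyfit-Mr per-pixel extraction over a cleaned cube.

    Per pixel: climatology -> degree-6 fit -> rate-of-change thresholds
    -> per-year dating (see :func:`date_year` for ``year_smoother``) ->
    GSL = EOS - SOS. Masked pixels are flagged MASKED for every year.
    When ``snow_mask`` is given, SOS/EOS are clamped to the first/last
    snow-free composite window of each year (thermal growing season) and
    clamp events recorded.
    """
    if ndvi.cadence != "composite-15d":
        raise ValueError("extract_phenology needs a composite-15d cube")
    ym, uyears, mid_days = _year_matrix(ndvi)
    n_years = len(uyears)
    n_rows, n_cols = ndvi.grid.shape
    sos = np.full((n_years, n_rows, n_cols), np.nan)
    eos = np.full_like(sos, np.nan)
    flags = np.full(sos.shape, int(Flag.FIT_FAILED), dtype=np.int8)
    sos_cl = np.zeros(sos.shape, dtype=bool)
    eos_cl = np.zeros(sos.shape, dtype=bool)

    if snow_mask is not None:
        snow_ym = np.zeros((n_years, 24, n_rows, n_cols), dtype=bool)
        syears = pd.DatetimeIndex(snow_mask.times).year.to_numpy()
        sdoys = pd.DatetimeIndex(snow_mask.times).dayofyear.to_numpy()
        sk = np.minimum((sdoys - 1) // 15, 23)
        snow_ym[np.searchsorted(uyears, syears), sk] = snow_mask.flags
        win_start = np.arange(24) * 15 + 1
        win_end = win_start + 14
        win_end[-1] = 365

    for r in range(n_rows):
        for c in range(n_cols):
            if mask is not None and not mask.valid[r, c]:
                flags[:, r, c] = Flag.MASKED
                continue
            series = ym[:, :, r, c]
            try:
                clim = climatology(series)
                thresholds = derive_thresholds(
                    fit_polynomial(clim, mid_days, refine=refine)
                )
            except (FitError, ValueError):
                continue  # stays FIT_FAILED
            for yi in range(n_years):
                s, e, flag = date_year(
                    series[yi], mid_days, thresholds,
                    year_smoother=year_smoother, refine=refine,
                )
                if snow_mask is not None and flag == Flag.OK:
                    free = np.flatnonzero(~snow_ym[yi, :, r, c])
                    if free.size:
                        lo = float(win_start[free[0]])
                        hi = float(win_end[free[-1]])
                        if s < lo:
                            s, sos_cl[yi, r, c] = lo, True
                        if e > hi:
                            e, eos_cl[yi, r, c] = hi, True
                sos[yi, r, c], eos[yi, r, c] = s, e
                flags[yi, r, c] = flag
    gsl = eos - sos
    return PhenologySeries(
        uyears, sos, eos, gsl, flags, ndvi.grid, sos_cl, eos_cl
    )
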