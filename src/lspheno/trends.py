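"""Per-pixel linear trends of phenological metrics and class summaries.

Trends are ordinary least-squares regressions of the yearly metric on the
calendar year, per pixel; significance is the two-sided t-test on the
slope. Class summaries stratify the per-pixel slopes by grouped land
cover: mean and spread of the slope over *significant* pixels (p < alpha)
and the percentage of valid class pixels with significant positive /
negative slopes. No multiple-testing correction is applied by default,
matching the per-pixel p < 0.05 convention of this kind of analysis; a
Benjamini-Hochberg option exists for sensitivity checks.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import GROUPED4, LandCoverMap
from .phenology import Flag, PhenologySeries

METRICS = ("sos", "eos", "gsl")


@dataclass
class TrendResult:
    metric: str
    slope: float  # days per year
    intercept: float
    p_value: float
    n_years: int


def pixel_trend(
    years: np.ndarray, values: np.ndarray, metric: str = ""
) -> TrendResult | None:
    """OLS slope of ``values`` on ``years`` with a two-sided slope t-test.

    Missing values are dropped pairwise; fewer than 3 complete pairs
    returns None.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values) & np.isfinite(years)
    x, y = years[keep], values[keep]
    n = x.size
    if n < 3:
        return None
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        return None
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sse = np.sum(resid**2)
    if n > 2:
        se = np.sqrt(sse / (n - 2) / sxx)
        if se == 0:
            p = 0.0 if slope != 0 else 1.0
        else:
            t = slope / se
            p = 2.0 * stats.t.sf(abs(t), n - 2)
    else:  # pragma: no cover - n >= 3 enforced above
        p = np.nan
    return TrendResult(metric, float(slope), float(intercept), float(p), int(n))


@dataclass
class TrendMap:
    """Per-pixel trend fields for one metric: (rows, cols) arrays."""

    metric: str
    slope: np.ndarray
    intercept: np.ndarray
    p_value: np.ndarray
    n_years: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.slope)


def metric_trends(pheno: PhenologySeries, metric: str) -> TrendMap:
    """Pixel-level trend of one metric over the record.

    Years whose quality flag is not OK are dropped pairwise.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    data = getattr(pheno, metric)
    ok = pheno.flags == Flag.OK
    values = np.where(ok, data, np.nan)
    n_rows, n_cols = values.shape[1:]
    slope = np.full((n_rows, n_cols), np.nan)
    intercept = np.full_like(slope, np.nan)
    p = np.full_like(slope, np.nan)
    n = np.zeros((n_rows, n_cols), dtype=np.int32)
    for r in range(n_rows):
        for c in range(n_cols):
            res = pixel_trend(pheno.years, values[:, r, c], metric)
            if res is None:
                continue
            slope[r, c] = res.slope
            intercept[r, c] = res.intercept
            p[r, c] = res.p_value
            n[r, c] = res.n_years
    return TrendMap(metric, slope, intercept, p, n)


def all_trends(pheno: PhenologySeries) -> dict[str, TrendMap]:
    return {m: metric_trends(pheno, m) for m in METRICS}


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values over the finite entries."""
    out = np.full_like(p, np.nan)
    idx = np.flatnonzero(np.isfinite(p.ravel()))
    if idx.size == 0:
        return out
    flat = p.ravel()[idx]
    order = np.argsort(flat)
    m = flat.size
    adj = flat[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.clip(adj, 0, 1)
    out.ravel()[idx] = res
    return out


def summarize_by_class(
    trends: dict[str, TrendMap] | TrendMap,
    landcover: LandCoverMap,
    alpha: float = 0.05,
    significant_only: bool = True,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Land-cover-stratified trend table (one row per metric x class).

    ``mean_slope``/``sd_slope`` are over pixels significant at ``alpha``
    (NaN when no pixel qualifies; set ``significant_only=False`` for
    all-valid-pixel means); ``pct_positive``/``pct_negative`` are the
    percentages of the class's valid pixels with significant positive /
    negative slopes. Empty classes are emitted with zero counts.
    """
    if landcover.scheme != "grouped-4":
        raise ValueError("summaries need a grouped-4 land-cover map")
    if isinstance(trends, TrendMap):
        trends = {trends.metric: trends}
    rows = []
    for metric, tm in trends.items():
        if landcover.codes.shape != tm.slope.shape:
            raise ValueError("land cover not on the trend grid")
        p = _bh_adjust(tm.p_value) if bh_correction else tm.p_value
        for code, name in GROUPED4.items():
            in_class = (landcover.codes == code) & tm.valid
            n_valid = int(in_class.sum())
            sig = in_class & (p < alpha)
            pos = sig & (tm.slope > 0)
            neg = sig & (tm.slope < 0)
            pool = sig if significant_only else in_class
            slopes = tm.slope[pool]
            rows.append(
                {
                    "metric": metric,
                    "class": name,
                    "mean_slope": float(np.mean(slopes)) if slopes.size else np.nan,
                    "sd_slope": float(np.std(slopes, ddof=1))
                    if slopes.size > 1
                    else np.nan,
                    "pct_positive": 100.0 * pos.sum() / n_valid if n_valid else 0.0,
                    "pct_negative": 100.0 * neg.sum() / n_valid if n_valid else 0.0,
                    "n_valid": n_valid,
                    "n_significant": int(sig.sum()),
                }
            )
    return pd.DataFrame(rows)


def area_fraction_significant(
    trends: TrendMap,
    mask: np.ndarray | None = None,
    sign: str = "negative",
    alpha: float = 0.05,
) -> float:
    """Percent of valid (optionally masked) pixels with a significant slope
    of the given sign ('positive', 'negative' or 'nonsignificant')."""
    valid = trends.valid
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
    n = int(valid.sum())
    if n == 0:
        return 0.0
    sig = valid & (trends.p_value < alpha)
    if sign == "positive":
        hit = sig & (trends.slope > 0)
    elif sign == "negative":
        hit = sig & (trends.slope < 0)
    elif sign == "nonsignificant":
        hit = valid & ~sig
    else:
        raise ValueError(f"unknown sign {sign!r}")
    return 100.0 * hit.sum() / n


def implied_gsl_trend(sos_slope: float, eos_slope: float) -> float:
    """GSL slope implied by SOS and EOS slopes over a shared pixel set.

    Because GSL = EOS - SOS year by year, OLS linearity gives
    slope(GSL) = slope(EOS) - slope(SOS) exactly.
    """
    return eos_slope - sos_slope


def gsl_expansion(sos_slope: float, eos_slope: float, n_years: int) -> float:
    """Total GSL change (days) implied over an ``n_years`` study period."""
    return implied_gsl_trend(sos_slope, eos_slope) * n_years
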