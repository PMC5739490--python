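"""Synthetic gridded scenes with known phenological ground truth.

The generator emulates the statistical structure the pipeline assumes:

* NDVI follows a double-logistic seasonal cycle sampled at 24 fifteen-day
  composite midpoints per year, plus zero-mean observation noise;
* the true spring/autumn inflection days drift linearly across years
  (configurable trends in days per year) with Gaussian interannual jitter;
* monthly climate anomalies (temperature, precipitation, insolation) live
  on a coarser climate grid and feed the inflection days through preseason
  couplings with a configurable lag, so the true attribution signs and the
  true preseason window are known by construction;
* daily near-surface temperature is a sinusoidal annual cycle plus AR(1)
  noise, so multi-day frost runs arise naturally in winter, and composites
  whose window overlaps a frost run are (with some probability) corrupted
  upward to mimic snow contamination of the NDVI signal;
* land cover is laid out in quadrant blocks (grassland / shrubland /
  forest / barren), so class-stratified summaries have known membership.

Everything is driven by one integer seed; a fixed seed reproduces every
array bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grids import (
    COMPOSITE_DOYS,
    FOREST,
    GRASSLAND,
    GROUPED4,
    OTHER,
    SHRUBLAND,
    GridSpec,
    LandCoverMap,
    RasterCube,
    month_of_day,
)
from .preprocess import detect_snow

#: IGBP code assigned to each grouped quadrant (exercises reclassification).
_QUADRANT_IGBP = {GRASSLAND: 10, SHRUBLAND: 7, FOREST: 3, OTHER: 16}

#: Monthly climatological bases for the climate cubes: precipitation (mm,
#: semi-arid continental, ~240 mm yr^-1, summer peak) and insolation
#: (MJ m^-2 month^-1, mid-latitude cycle).
_PRECIP_BASE = np.array([2, 3, 5, 10, 25, 45, 60, 50, 22, 10, 5, 3], dtype=float)
_INSOL_BASE = np.array(
    [150, 250, 400, 500, 600, 650, 620, 520, 400, 260, 160, 120], dtype=float
)


@dataclass(frozen=True)
class ClassPhenology:
    """Double-logistic parameters of one land-cover class.

    NDVI(d) = w + (m - w) * [sigma(a*(d - S)) - sigma(b*(d - A))] with the
    standard logistic sigma; ``s0``/``a0`` are the mean spring/autumn
    inflection days (day-of-year, 1-based), ``a``/``b`` the logistic slopes
    (per day).
    """

    w: float
    m: float
    s0: float
    a0: float
    a: float = 0.10
    b: float = 0.08

    def __post_init__(self) -> None:
        if not (self.w < self.m <= 1.0):
            raise ValueError("need winter NDVI w < summer NDVI m <= 1")
        if not (1 <= self.s0 < self.a0 <= 365):
            raise ValueError("need 1 <= s0 < a0 <= 365")


#: Per-class seasonal-cycle parameters. Inflection days are chosen so the
#: whole cycle (greenup start through senescence end) sits inside the
#: frost-free season of the default temperature cycle — the structural
#: premise of the snow rule (contamination confined to the non-growing
#: season) and consistent with the steppe environments this emulates
#: (mean autumn dates around day 250-290).
DEFAULT_CLASS_PARAMS: dict[int, ClassPhenology] = {
    GRASSLAND: ClassPhenology(w=0.12, m=0.55, s0=130, a0=270, a=0.10, b=0.10),
    SHRUBLAND: ClassPhenology(w=0.10, m=0.40, s0=140, a0=265, a=0.09, b=0.10),
    FOREST: ClassPhenology(w=0.15, m=0.75, s0=120, a0=275, a=0.12, b=0.10),
    # barren block: mean annual NDVI < 0.1, excluded by the vegetation mask
    OTHER: ClassPhenology(w=0.03, m=0.08, s0=150, a0=255, a=0.08, b=0.08),
}


@dataclass
class SceneConfig:
    """Full parameterisation of a synthetic scene.

    Trends are in days per year (negative SOS trend = advancing spring);
    couplings in days per unit preseason anomaly (°C for temperature,
    mm for the precipitation sum). ``beta_t_sos`` > 0 means a warm
    preseason *advances* spring; ``beta_t_eos``/``beta_p_eos`` > 0 mean a
    warm/wet preseason *delays* autumn.
    """

    grid: GridSpec = field(
        default_factory=lambda: GridSpec(10, 10, 0.1, (100.0, 50.0), "scene")
    )
    year_start: int = 1982
    year_end: int = 2011
    seed: int = 0
    class_params: dict[int, ClassPhenology] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    sos_trend: float = -0.10
    eos_trend: float = 0.11
    interannual_sd: float = 2.0
    noise_sd: float = 0.02
    snow_spike_prob: float = 0.5
    snow_spike_magnitude: float = 0.15
    beta_t_sos: float = 3.0
    beta_t_eos: float = 1.5
    beta_p_eos: float = 0.15
    coupling_lag: int = 2
    climate_factor: int = 5
    # Daily-temperature cycle tuned so the frost season (sub-zero runs)
    # sits inside the non-growing season: zero crossings near days 55/340,
    # well clear of the default greenup/senescence windows even allowing
    # for the AR(1) noise that lets frost runs spill past the crossings.
    temp_mean: float = 10.0
    temp_amplitude: float = 13.0
    temp_ar: float = 0.75
    temp_noise_sd: float = 2.5
    t_anom_sd: float = 1.0
    p_anom_sd: float = 8.0
    i_anom_sd: float = 30.0

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def climate_grid(self) -> GridSpec:
        return self.grid.coarsen(self.climate_factor, id="climate")

    def validate(self) -> None:
        if self.year_end < self.year_start:
            raise ValueError("year_end < year_start")
        if not 0 <= self.coupling_lag <= 5:
            raise ValueError("coupling lag must be 0..5 months")
        for code, cp in self.class_params.items():
            if code not in GROUPED4:
                raise ValueError(f"unknown grouped class code {code}")
            for day in (cp.s0, cp.a0):
                if month_of_day(day) - self.coupling_lag < 1:
                    raise ValueError(
                        "preseason window would cross the year boundary; "
                        f"event day {day} with lag {self.coupling_lag}"
                    )


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests.

    ``s``/``a`` are the true spring/autumn inflection days, (year, row,
    col). The stored climate anomalies are the *effective* ones (after
    non-negativity truncation of precipitation) on the climate grid, i.e.
    exactly the quantities that entered the inflection days.
    """

    years: np.ndarray
    s: np.ndarray
    a: np.ndarray
    sos_trend: float
    eos_trend: float
    couplings: dict[str, float]
    coupling_lag: int
    climate_grid: GridSpec
    t_anom: np.ndarray  # (n_years*12, rows_c, cols_c)
    p_anom: np.ndarray
    i_anom: np.ndarray
    clean_ndvi: np.ndarray  # noise-free, uncontaminated composite NDVI
    snow_contaminated: np.ndarray  # bool, (time, row, col)

    def to_dataframe(self) -> pd.DataFrame:
        n_years, n_rows, n_cols = self.s.shape
        yy, rr, cc = np.meshgrid(
            self.years, np.arange(n_rows), np.arange(n_cols), indexing="ij"
        )
        return pd.DataFrame(
            {
                "year": yy.ravel(),
                "row": rr.ravel(),
                "col": cc.ravel(),
                "true_sos": self.s.ravel(),
                "true_eos": self.a.ravel(),
            }
        )


@dataclass
class Scene:
    ndvi: RasterCube
    daily_temp: RasterCube
    temperature: RasterCube
    precipitation: RasterCube
    insolation: RasterCube
    landcover: LandCoverMap
    truth: GroundTruth


# --- helpers ------------------------------------------------------------

def _sigma(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def quadrant_landcover(grid: GridSpec) -> LandCoverMap:
    """IGBP map with one class per quadrant (NW grass, NE shrub, SW forest,
    SE barren)."""
    codes = np.empty(grid.shape, dtype=np.int64)
    half_r, half_c = grid.n_rows // 2, grid.n_cols // 2
    codes[:half_r, :half_c] = _QUADRANT_IGBP[GRASSLAND]
    codes[:half_r, half_c:] = _QUADRANT_IGBP[SHRUBLAND]
    codes[half_r:, :half_c] = _QUADRANT_IGBP[FOREST]
    codes[half_r:, half_c:] = _QUADRANT_IGBP[OTHER]
    return LandCoverMap(codes, grid, "IGBP-17")


def _grouped_codes(grid: GridSpec) -> np.ndarray:
    codes = np.empty(grid.shape, dtype=np.int64)
    half_r, half_c = grid.n_rows // 2, grid.n_cols // 2
    codes[:half_r, :half_c] = GRASSLAND
    codes[:half_r, half_c:] = SHRUBLAND
    codes[half_r:, :half_c] = FOREST
    codes[half_r:, half_c:] = OTHER
    return codes


def _expand(coarse: np.ndarray, factor: int) -> np.ndarray:
    """Repeat the trailing two (row, col) axes ``factor`` times each."""
    return np.repeat(np.repeat(coarse, factor, axis=-2), factor, axis=-1)


def _preseason_anomaly(
    anom: np.ndarray, month: int, lag: int, how: str
) -> np.ndarray:
    """Aggregate monthly anomalies over [month-lag, month] per year.

    ``anom`` is (n_years*12, rows, cols); returns (n_years, rows, cols),
    NaN for years whose window starts before the record.
    """
    n_years = anom.shape[0] // 12
    out = np.full((n_years,) + anom.shape[1:], np.nan)
    for yi in range(n_years):
        end = yi * 12 + month - 1
        start = end - lag
        if start < 0:
            continue
        win = anom[start : end + 1]
        out[yi] = win.mean(axis=0) if how == "mean" else win.sum(axis=0)
    return out


def _daily_base_temperature(doys: np.ndarray, mean: float, amp: float) -> np.ndarray:
    """Annual temperature cycle, coldest in mid-January."""
    d = np.minimum(doys, 365)
    return mean - amp * np.cos(2 * np.pi * (d - 15) / 365.0)


def _composite_times(years: np.ndarray) -> np.ndarray:
    dates = []
    for y in years:
        start = np.datetime64(f"{y}-01-01")
        dates.append(start + (COMPOSITE_DOYS - 1).astype("timedelta64[D]"))
    return np.concatenate(dates)


def _monthly_times(years: np.ndarray) -> np.ndarray:
    return np.array(
        [np.datetime64(f"{y}-{m:02d}-15") for y in years for m in range(1, 13)],
        dtype="datetime64[D]",
    )


# --- generation ---------------------------------------------------------

def generate_scene(config: SceneConfig) -> Scene:
    """Generate a full synthetic scene plus its ground truth.

    Draw order (fixed for reproducibility): monthly climate anomalies,
    interannual phenology jitter, daily-temperature AR(1) innovations,
    NDVI observation noise, snow-spike Bernoulli draws, spike magnitudes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    cgrid = config.climate_grid
    years = config.years
    n_years = config.n_years
    n_months = n_years * 12
    cshape = (cgrid.n_rows, cgrid.n_cols)

    # 1. climate anomalies on the climate grid
    t_anom = rng.normal(0.0, config.t_anom_sd, (n_months,) + cshape)
    p_anom = rng.normal(0.0, config.p_anom_sd, (n_months,) + cshape)
    i_anom = rng.normal(0.0, config.i_anom_sd, (n_months,) + cshape)
    # truncate precipitation at zero and keep the effective anomaly
    p_base = np.tile(_PRECIP_BASE, n_years)[:, None, None]
    p_total = np.maximum(p_base + p_anom, 0.0)
    p_anom = p_total - p_base

    # 2. interannual jitter
    eps_s = rng.normal(0.0, config.interannual_sd, (n_years,) + grid.shape)
    eps_a = rng.normal(0.0, config.interannual_sd, (n_years,) + grid.shape)

    # 3. true inflection days per pixel-year
    grouped = _grouped_codes(grid)
    s0_map = np.empty(grid.shape)
    a0_map = np.empty(grid.shape)
    a_map = np.empty(grid.shape)
    b_map = np.empty(grid.shape)
    w_map = np.empty(grid.shape)
    m_map = np.empty(grid.shape)
    for code, cp in config.class_params.items():
        sel = grouped == code
        s0_map[sel], a0_map[sel] = cp.s0, cp.a0
        a_map[sel], b_map[sel] = cp.a, cp.b
        w_map[sel], m_map[sel] = cp.w, cp.m

    dy = (years - years[0])[:, None, None].astype(float)
    s_true = s0_map[None] + config.sos_trend * dy + eps_s
    a_true = a0_map[None] + config.eos_trend * dy + eps_a
    lag = config.coupling_lag
    for code, cp in config.class_params.items():
        sel = grouped == code
        m_sos = month_of_day(cp.s0)
        m_eos = month_of_day(cp.a0)
        t_pre_sos = _expand(
            _preseason_anomaly(t_anom, m_sos, lag, "mean"), config.climate_factor
        )
        t_pre_eos = _expand(
            _preseason_anomaly(t_anom, m_eos, lag, "mean"), config.climate_factor
        )
        p_pre_eos = _expand(
            _preseason_anomaly(p_anom, m_eos, lag, "sum"), config.climate_factor
        )
        s_true[:, sel] -= config.beta_t_sos * t_pre_sos[:, sel]
        a_true[:, sel] += (
            config.beta_t_eos * t_pre_eos[:, sel]
            + config.beta_p_eos * p_pre_eos[:, sel]
        )
    if np.any(s_true >= a_true):
        n_bad = int(np.sum(s_true >= a_true))
        raise ValueError(
            f"configuration pushes spring past autumn in {n_bad} pixel-years; "
            "reduce trends/couplings or widen s0..a0"
        )

    # 4. daily temperature with AR(1) noise
    daily_times = pd.date_range(
        f"{config.year_start}-01-01", f"{config.year_end}-12-31", freq="D"
    ).values.astype("datetime64[D]")
    doys = pd.DatetimeIndex(daily_times).dayofyear.to_numpy()
    base = _daily_base_temperature(doys, config.temp_mean, config.temp_amplitude)
    innov = rng.normal(0.0, config.temp_noise_sd, (len(daily_times),) + grid.shape)
    from scipy.signal import lfilter

    ar_noise = lfilter([1.0], [1.0, -config.temp_ar], innov, axis=0)
    daily_vals = base[:, None, None] + ar_noise
    daily_temp = RasterCube(
        daily_vals, daily_times, "daily", grid, "temperature", "degC"
    )

    # 5. clean NDVI at composite midpoints
    comp_times = _composite_times(years)
    d = COMPOSITE_DOYS.astype(float)[None, :, None, None]  # (1, 24, 1, 1)
    s4 = s_true[:, None]  # (years, 1, r, c)
    a4 = a_true[:, None]
    curve = w_map + (m_map - w_map) * (
        _sigma(a_map * (d - s4)) - _sigma(b_map * (d - a4))
    )
    clean = curve.reshape(n_years * 24, *grid.shape)

    # 6. observation noise, then snow spikes on frozen-window composites
    noise = rng.normal(0.0, config.noise_sd, clean.shape)
    obs = clean + noise
    frozen = detect_snow(daily_temp, comp_times).flags
    hit = frozen & (rng.uniform(size=clean.shape) < config.snow_spike_prob)
    spike = config.snow_spike_magnitude * rng.uniform(0.5, 1.5, clean.shape)
    obs = np.clip(obs + np.where(hit, spike, 0.0), -1.0, 1.0)
    ndvi = RasterCube(obs, comp_times, "composite-15d", grid, "ndvi", "1")

    truth = GroundTruth(
        years=years,
        s=s_true,
        a=a_true,
        sos_trend=config.sos_trend,
        eos_trend=config.eos_trend,
        couplings={
            "beta_t_sos": config.beta_t_sos,
            "beta_t_eos": config.beta_t_eos,
            "beta_p_eos": config.beta_p_eos,
        },
        coupling_lag=lag,
        climate_grid=cgrid,
        t_anom=t_anom,
        p_anom=p_anom,
        i_anom=i_anom,
        clean_ndvi=clean,
        snow_contaminated=hit,
    )
    temperature, precipitation, insolation = generate_climate_series(config, truth)
    return Scene(
        ndvi=ndvi,
        daily_temp=daily_temp,
        temperature=temperature,
        precipitation=precipitation,
        insolation=insolation,
        landcover=quadrant_landcover(grid),
        truth=truth,
    )


def generate_climate_series(
    config: SceneConfig, truth: GroundTruth
) -> tuple[RasterCube, RasterCube, RasterCube]:
    """Monthly climate cubes from the anomalies stored in ``truth``.

    Each cube is a seasonal climatological base plus the (effective)
    anomaly that entered the true inflection days, so the true preseason
    lag and partial-correlation signs are recoverable by construction.
    Precipitation is non-negative.
    """
    cgrid = truth.climate_grid
    years = truth.years
    n_years = len(years)
    times = _monthly_times(years)
    doys = pd.DatetimeIndex(times).dayofyear.to_numpy()
    t_base = _daily_base_temperature(doys, config.temp_mean, config.temp_amplitude)
    t_vals = t_base[:, None, None] + truth.t_anom
    p_vals = np.tile(_PRECIP_BASE, n_years)[:, None, None] + truth.p_anom
    i_vals = np.tile(_INSOL_BASE, n_years)[:, None, None] + truth.i_anom
    i_vals = np.maximum(i_vals, 0.0)
    return (
        RasterCube(t_vals, times, "monthly", cgrid, "temperature", "degC"),
        RasterCube(p_vals, times, "monthly", cgrid, "precipitation", "mm"),
        RasterCube(i_vals, times, "monthly", cgrid, "insolation", "MJ m-2"),
    )


def config_from_dict(data: dict) -> SceneConfig:
    """Build a SceneConfig from a plain dict (e.g. parsed YAML)."""
    data = dict(data)
    if "grid" in data:
        g = data["grid"]
        data["grid"] = GridSpec(
            g["n_rows"], g["n_cols"], g["cell_size"],
            tuple(g.get("origin", (0.0, 0.0))), g.get("id", "scene"),
        )
    if "class_params" in data:
        data["class_params"] = {
            int(code): ClassPhenology(**params)
            for code, params in data["class_params"].items()
        }
    return SceneConfig(**data)


def config_to_dict(config: SceneConfig) -> dict:
    out = asdict(config)
    out["grid"] = {
        "n_rows": config.grid.n_rows,
        "n_cols": config.grid.n_cols,
        "cell_size": config.grid.cell_size,
        "origin": list(config.grid.origin),
        "id": config.grid.id,
    }
    out["class_params"] = {
        int(code): asdict(cp) for code, cp in config.class_params.items()
    }
    return out
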