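import numpy as np
import pytest

from lspheno import (
    GridSpec,
    LandCoverMap,
    RasterCube,
    aggregate_phenology,
    attribute,
    climate_trend,
    partial_correlation,
    preseason_series,
    select_lag,
    summarize_attribution,
)
from lspheno.attribution import PreseasonSpec
from lspheno.phenology import Flag, PhenologySeries

YEARS = np.arange(1982, 2012)


def _monthly_cube(values, variable, grid=None):
    values = np.asarray(values, dtype=float)
    n_years = values.shape[0] // 12
    times = np.array(
        [
            np.datetime64(f"{1982 + y}-{m:02d}-15")
            for y in range(n_years)
            for m in range(1, 13)
        ],
        dtype="datetime64[D]",
    )
    grid = grid or GridSpec(*values.shape[1:], 0.5)
    return RasterCube(values, times, "monthly", grid, variable)


class TestPartialCorrelation:
    def test_empty_controls_equals_pearson(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 1, 30)
        r, p, n = partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        assert n == 30

    def test_matches_residualization_oracle(self, rng):
        """Precision-matrix partial r must equal the correlation of the
        residuals after regressing x and y on the controls (1e-10)."""
        for _ in range(1000):
            n = int(rng.integers(10, 40))
            k = int(rng.integers(1, 3))
            Z = rng.normal(0, 1, (n, k))
            x = Z @ rng.normal(0, 1, k) + rng.normal(0, 1, n)
            y = Z @ rng.normal(0, 1, k) + x * rng.uniform(-1, 1) + rng.normal(0, 1, n)
            r, p, _ = partial_correlation(x, y, tuple(Z.T))
            A = np.column_stack([np.ones(n), Z])
            rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
            ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_matches_classical_recursion_single_control(self, rng):
        """r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        for _ in range(1000):
            data = rng.normal(0, 1, (12, 3))
            data[:, 1] += 0.5 * data[:, 0]
            data[:, 2] += 0.3 * data[:, 0]
            x, y, z = data.T
            r, _, _ = partial_correlation(x, y, (z,))
            rxy = np.corrcoef(x, y)[0, 1]
            rxz = np.corrcoef(x, z)[0, 1]
            ryz = np.corrcoef(y, z)[0, 1]
            expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            assert r == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        df = pd.DataFrame(rng.normal(0, 1, (25, 4)), columns=list("xyzw"))
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z", "w"])
        r, p, _ = partial_correlation(
            df["x"].to_numpy(), df["y"].to_numpy(),
            (df["z"].to_numpy(), df["w"].to_numpy()),
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_constant_series_gives_missing(self):
        x = np.arange(30.0)
        y = np.random.default_rng(0).normal(0, 1, 30)
        r, p, _ = partial_correlation(x, y, (np.full(30, 2.0),))
        assert np.isnan(r) and np.isnan(p)

    def test_insufficient_years_missing(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p, n = partial_correlation(x, x, (x, x))
        assert np.isnan(r) and n == 4


class TestPreseason:
    def test_aggregation_convention_fixed_per_variable(self):
        spec = PreseasonSpec("sos", "temperature", 2, "mean")
        assert spec.aggregation == "mean"
        with pytest.raises(ValueError, match="sum"):
            PreseasonSpec("sos", "precipitation", 2, "mean")
        with pytest.raises(ValueError, match="lag"):
            PreseasonSpec("sos", "temperature", 7, "mean")

    def test_lag0_equals_event_month_value(self):
        vals = np.arange(24.0).reshape(24, 1, 1)
        cube = _monthly_cube(vals, "temperature")
        month = np.array([[5]])
        out = preseason_series(cube, month, lag=0)
        assert out[0, 0, 0] == pytest.approx(vals[4, 0, 0])
        assert out[1, 0, 0] == pytest.approx(vals[16, 0, 0])

    def test_temperature_mean_precipitation_sum(self):
        vals = np.zeros((12, 1, 1))
        vals[0:3, 0, 0] = [1.0, 2.0, 3.0]  # Jan, Feb, Mar
        month = np.array([[3]])
        t = preseason_series(_monthly_cube(vals, "temperature"), month, lag=2)
        assert t[0, 0, 0] == pytest.approx(2.0)  # mean of 1,2,3
        vals[0:3, 0, 0] = [10.0, 20.0, 30.0]
        p = preseason_series(_monthly_cube(vals, "precipitation"), month, lag=2)
        assert p[0, 0, 0] == pytest.approx(60.0)  # sum

    def test_window_before_record_start_missing(self):
        vals = np.ones((24, 1, 1))
        out = preseason_series(
            _monthly_cube(vals, "temperature"), np.array([[2]]), lag=4
        )
        assert np.isnan(out[0, 0, 0])  # Feb of first year needs prior October
        assert np.isfinite(out[1, 0, 0])


class TestSelectLag:
    def test_picks_generating_lag(self, rng):
        hits = 0
        n_cells = 200
        for _ in range(n_cells):
            monthly = rng.normal(0, 1, (30, 6))  # per-lag candidate windows
            signal = monthly[:, 2]
            event = -3.0 * signal + rng.normal(0, 1, 30)
            series = {lag: monthly[:, lag] for lag in range(6)}
            series[2] = signal
            pick = select_lag(event, series)
            hits += pick is not None and pick[0] == 2
        assert hits >= 0.9 * n_cells

    def test_tie_breaks_toward_shorter_lag(self):
        event = np.arange(30.0)
        series = {0: event.copy(), 3: event.copy()}  # identical |r| = 1
        pick = select_lag(event, series)
        assert pick[0] == 0

    def test_requires_min_overlap(self):
        event = np.full(30, np.nan)
        event[:8] = np.arange(8.0)
        assert select_lag(event, {0: np.arange(30.0)}, min_years=10) is None


class TestAggregatePhenology:
    def _pheno(self, sos, flags=None):
        sos = np.asarray(sos, dtype=float)
        n_years = sos.shape[0]
        grid = GridSpec(*sos.shape[1:], 0.1)
        if flags is None:
            flags = np.where(np.isfinite(sos), Flag.OK, Flag.NO_SOS_CROSSING)
        eos = sos + 100.0
        return PhenologySeries(
            np.arange(2000, 2000 + n_years), sos, eos, eos - sos,
            np.asarray(flags, dtype=np.int8), grid,
        )

    def test_single_valid_pixel_cell_mean(self):
        sos = np.full((1, 2, 2), np.nan)
        sos[0, 0, 0] = 120.0
        pheno = self._pheno(sos)
        out = aggregate_phenology(pheno, pheno.grid.coarsen(2), min_valid_frac=0.25)
        assert out["sos"][0, 0, 0] == pytest.approx(120.0)

    def test_mean_of_two_pixels(self):
        sos = np.full((1, 2, 2), np.nan)
        sos[0, 0, :] = [100.0, 110.0]
        out = aggregate_phenology(
            self._pheno(sos), GridSpec(1, 1, 0.2), min_valid_frac=0.5
        )
        assert out["sos"][0, 0, 0] == pytest.approx(105.0)

    def test_below_half_coverage_is_missing(self):
        # 3 of 8 finite values in the first two rows of a 4x4 -> one 2x4...
        sos = np.full((1, 4, 4), np.nan)
        sos[0, 0, 0] = sos[0, 0, 1] = sos[0, 1, 0] = 120.0  # 3 of 16 pixels
        out = aggregate_phenology(self._pheno(sos), GridSpec(1, 1, 0.4))
        assert np.isnan(out["sos"][0, 0, 0])
        sos[0, 1, 1:4] = 120.0
        sos[0, 2, 0:2] = 120.0  # now 8 of 16 -> exactly half, kept
        out = aggregate_phenology(self._pheno(sos), GridSpec(1, 1, 0.4))
        assert np.isfinite(out["sos"][0, 0, 0])

    def test_non_ok_flags_excluded(self):
        sos = np.full((1, 2, 2), 130.0)
        flags = np.full((1, 2, 2), Flag.OK, dtype=np.int8)
        flags[0, 0, 0] = Flag.FIT_FAILED
        sos[0, 0, 0] = 999.0  # must not leak into the mean
        out = aggregate_phenology(
            self._pheno(sos, flags), GridSpec(1, 1, 0.2), min_valid_frac=0.5
        )
        assert out["sos"][0, 0, 0] == pytest.approx(130.0)


class TestAttributePipeline:
    def test_mechanism_signs_recovered(self, coupled_scene):
        """Warm preseason -> earlier SOS and wet preseason -> later EOS in
        the generator must come back as negative temperature-SOS and
        positive precipitation-EOS partial correlations."""
        import lspheno as lp

        scene = coupled_scene
        snow = lp.detect_snow(scene.daily_temp, scene.ndvi.times)
        clean = lp.replace_snow(scene.ndvi, snow)
        pheno = lp.extract_phenology(clean, lp.vegetation_mask(clean))
        cells = aggregate_phenology(pheno, scene.temperature.grid)
        res = attribute(
            cells,
            {
                "temperature": scene.temperature,
                "precipitation": scene.precipitation,
                "insolation": scene.insolation,
            },
        )
        ts = res[(res.event == "sos") & (res.variable == "temperature")]
        ts = ts[np.isfinite(ts.partial_r)]
        assert len(ts) >= 8
        assert (ts.partial_r < 0).mean() >= 0.8
        sig = ts[ts.p_value < 0.05]
        assert len(sig) >= 0.5 * len(ts)
        pe = res[(res.event == "eos") & (res.variable == "precipitation")]
        pe = pe[np.isfinite(pe.partial_r)]
        assert (pe.partial_r > 0).mean() >= 0.8
        # the generating preseason lag dominates the selected lags
        assert (pe.lag == scene.truth.coupling_lag).mean() >= 0.5

    def test_constant_precipitation_isolated(self):
        rng = np.random.default_rng(0)
        n_years = 30
        sos = 130 + rng.normal(0, 2, (n_years, 1, 1))
        eos = 270 + rng.normal(0, 2, (n_years, 1, 1))
        cells = {"sos": sos, "eos": eos, "years": YEARS}
        shape = (n_years * 12, 1, 1)
        climate = {
            "temperature": _monthly_cube(rng.normal(5, 1, shape), "temperature"),
            "precipitation": _monthly_cube(np.full(shape, 20.0), "precipitation"),
            "insolation": _monthly_cube(rng.normal(400, 30, shape), "insolation"),
        }
        res = attribute(cells, climate)
        prec = res[(res.event == "sos") & (res.variable == "precipitation")].iloc[0]
        assert np.isnan(prec.partial_r)
        temp = res[(res.event == "sos") & (res.variable == "temperature")].iloc[0]
        assert np.isfinite(temp.partial_r)


class TestSummarizeAttribution:
    def _results(self, partial_r, p, n=30):
        import pandas as pd

        rows = []
        for (r, c), pr in np.ndenumerate(partial_r):
            rows.append(
                dict(row=r, col=c, event="sos", variable="temperature",
                     lag=2, partial_r=pr, p_value=p[r, c], n_years=n)
            )
        return pd.DataFrame(rows)

    def test_all_significant_negative(self):
        res = self._results(np.full((2, 2), -0.8), np.full((2, 2), 0.001))
        lc = LandCoverMap(np.ones((2, 2), dtype=int), GridSpec(2, 2, 0.5), "grouped-4")
        table = summarize_attribution(res, lc)
        row = table[
            (table["class"] == "grassland") & (table.variable == "temperature")
            & (table.event == "sos")
        ].iloc[0]
        assert row.pct_negative == 100.0 and row.pct_positive == 0.0

    def test_matches_bruteforce_filter(self, rng):
        pr = rng.uniform(-1, 1, (4, 4))
        p = rng.uniform(0, 1, (4, 4))
        res = self._results(pr, p)
        codes = rng.integers(1, 5, (4, 4))
        lc = LandCoverMap(codes, GridSpec(4, 4, 0.5), "grouped-4")
        table = summarize_attribution(res, lc)
        for code, name in [(1, "grassland"), (2, "shrubland"), (3, "forest"), (4, "other")]:
            sel = codes == code
            n = sel.sum()
            row = table[
                (table["class"] == name) & (table.variable == "temperature")
                & (table.event == "sos")
            ].iloc[0]
            if n == 0:
                assert row.pct_positive == 0.0 and row.n_cells == 0
                continue
            sig_pos = (sel & (p < 0.05) & (pr > 0)).sum()
            sig_neg = (sel & (p < 0.05) & (pr < 0)).sum()
            assert row.pct_positive == pytest.approx(100.0 * sig_pos / n)
            assert row.pct_negative == pytest.approx(100.0 * sig_neg / n)

    def test_short_records_excluded(self):
        res = self._results(np.full((2, 2), -0.8), np.full((2, 2), 0.001), n=5)
        lc = LandCoverMap(np.ones((2, 2), dtype=int), GridSpec(2, 2, 0.5), "grouped-4")
        table = summarize_attribution(res, lc)
        assert (table.n_cells == 0).all()


class TestClimateTrend:
    def test_linear_warming_recovered(self):
        series = 0.05 * (YEARS - YEARS[0]) + 2.0
        res = climate_trend(series, YEARS)
        assert res.slope == pytest.approx(0.05, abs=1e-12)

    def test_constant_and_short_series(self):
        assert climate_trend(np.full(30, 3.0), YEARS).slope == pytest.approx(0.0)
        assert climate_trend(np.array([1.0, 2.0]), YEARS[:2]) is None
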