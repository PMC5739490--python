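# Methods

This note documents the models, defaults and numerical choices behind
`lspheno`, and what the synthetic scenes do and do not establish about
behaviour on real data.

## Data model

All grids are regular lon/lat grids; row 0 is the northernmost row, cell
coordinates refer to cell centers, and day-of-year values are 1-based.
Missing data are IEEE NaN in memory and `_FillValue`/NaN in CF-style
NetCDF (written with xarray's scipy engine, i.e. NetCDF-3 classic; this
is the only on-disk format — there is no GeoTIFF reader). A `RasterCube`
is a `(time, row, col)` array with strictly increasing timestamps and
one of four cadences (15-day composite, daily, monthly, annual); NDVI
cubes are validated to [−1, 1]. The 24 compositing windows per year are
days 1–15, 16–30, …, with days 361–365 absorbed into the last window and
composite timestamps placed at window midpoints (day 8, 23, …, 353);
the compositing calendar of real archives varies, and this convention is
an explicit, documented choice.

Land cover uses the 17-class IGBP legend grouped into grassland
(grassland, savanna and — configurably — woody savanna, which is a
savanna subclass), shrubland (closed + open), forest (evergreen and
deciduous needleleaf, deciduous broadleaf, mixed; evergreen broadleaf is
left in "other" because it does not occur in the steppe systems this
grouping was built for) and "other". Majority resampling to a coarser
grid requires nesting grids (integer cell-size ratio, shared origin) and
breaks ties toward the lowest grouped code (grassland < shrubland <
forest < other) — deterministic and reproducible.

## Snow rule and vegetation mask

A composite is flagged as potentially snow-covered iff its window
overlaps a run of at least five consecutive days with daily **mean**
temperature strictly below 0 °C at that pixel (whether the original
convention used daily mean, min or max is not derivable from the method
description; mean is the default and the statistic is configurable by
supplying a different daily cube). Flagged composites are replaced by
the same pixel's NDVI at the temporally nearest unflagged composite,
ties toward the earlier one; replacement is idempotent and never touches
unflagged values. The rule is applied to all flagged composites rather
than only outside a pre-declared growing season, because SOS/EOS are not
yet known at this stage; ≥5-day frost runs inside the growing season are
rare in the regimes the pipeline targets, making the difference
immaterial there. Pixels whose mean NDVI over the whole record is below
0.1 lack a usable seasonal cycle and are masked (strictly-below; a mean
of exactly 0.1 is kept). The mask is computed after snow replacement.

## Polyfit-Mr extraction

The climatology (per-composite mean over years, missing values ignored)
is fitted with a degree-6 polynomial on normalised day $t = d/365$. The
coefficients are solved by linear least squares and refined with
Levenberg–Marquardt (`scipy.optimize.least_squares`, gtol 1e-8, ≤1000
evaluations); for a model linear in its coefficients L-M converges to
the linear solution, which therefore serves as a built-in cross-check.
Normalisation keeps the Vandermonde matrix well conditioned; leap days
are folded onto day 365.

The climatological SOS (EOS) is the day in 1..365 where the analytic
first derivative of the fitted curve is largest (smallest). Because a
degree-6 polynomial fitted to a cycle with flat winter tails can swing
steeply at the year boundaries, the extrema are taken over *interior
local* extrema of the derivative, falling back to the global extremum
only when no interior candidate exists; a curve whose maximum rate of
change does not precede its minimum has no coherent seasonal cycle and
the pixel is flagged `fit_failed`. The fitted NDVI values at these two
days become the pixel's SOS/EOS thresholds.

Each year is then dated against these fixed thresholds: SOS is the first
upward crossing before the day of the annual maximum, EOS the first
downward crossing after it, linearly interpolated between integer days.
Two choices here deviate from the most literal reading of the published
procedure and are deliberate:

* **Per-year daily curve.** The default interpolates the year's
  composites linearly rather than refitting a degree-6 polynomial. The
  polynomial is a global basis: with opposing SOS and EOS drifts, the
  autumn change perturbs the fitted spring segment and vice versa, which
  measurably attenuates class-mean trends (up to ~35 % for low-amplitude
  classes on noiseless scenes) and breaks the premise that the dating
  bias is constant across years. Linear interpolation is local, has a
  transfer slope of ≈ 1 between true and dated shifts, and leaves only a
  constant offset that cancels in trends and correlations.
  `year_smoother="polynomial"` restores the refit variant.
* **First, not last, downward crossing for EOS.** Taking the last
  crossing of the year admits spurious re-crossings from curve wiggles
  near the year end (errors up to tens of days, correlated with the
  trend); the first crossing after the seasonal peak is robust. How the
  original procedure resolved multiple crossings is not stated.

GSL = EOS − SOS holds exactly for every dated record. When a snow mask
is supplied, dates are clamped to the first/last snow-free composite
window of the year (the thermal growing season); clamp events are
recorded in separate boolean fields rather than a quality flag, so the
flag vocabulary stays {ok, no_sos_crossing, no_eos_crossing, fit_failed,
masked}. Thresholds are per pixel, not per region.

## Trends

Per-pixel OLS of each metric on calendar year over the years whose
quality flag is `ok` (pairwise deletion, minimum three pairs), with the
two-sided t-test on the slope. Class summaries report mean and SD of the
slope over pixels significant at α (default 0.05) — the convention of
significance-filtered regional tables; an all-pixels option exists and is
what parameter-recovery checks use, since significance filtering selects
extreme slopes by construction. No multiple-testing correction is applied
by default, matching the per-pixel p < 0.05 convention; Benjamini–
Hochberg is available as an option. Because OLS is linear, the GSL slope
equals the EOS slope minus the SOS slope exactly on shared pixel-years
(`implied_gsl_trend`), which is also how the published per-class GSL
slopes relate to their SOS/EOS rows.

## Attribution

Fine-grid SOS/EOS dates are averaged into the coarse climate cells per
year; a cell-year is missing when fewer than half of its covered pixels
have an `ok` date. The preseason of an event in a cell is the window of
`lag` ∈ {0..5} calendar months ending in the month containing the
long-term mean event date (fixed across years — letting the month vary
per year would conflate timing and climate). Temperature is averaged
over the window; precipitation and insolation are summed. Per variable
the lag with the highest |Pearson r| against the event series is
selected (ties toward the shorter preseason; plain correlation, not
partial, mirroring the two-stage structure of the published analysis —
selection by partial r is available by computing it per lag). Partial
correlations come from the inverse of the joint correlation matrix over
complete years, with p from $t = r\sqrt{(n-2-k)/(1-r^2)}$ on $n-2-k$
degrees of freedom; a singular matrix (e.g. a constant series) yields a
missing result without affecting the other variables. For each event the
controls are the other two climate variables at their own selected lags;
the EOS–SOS partial correlation controls for the three EOS-preseason
climate variables (the control set of that relation is not documented in
the literature this mirrors — this is the package's choice). Series are
not detrended before correlation (no detrending step is documented;
chance trends therefore leak into the correlations, which the synthetic
tests quantify); cells with fewer than 10 complete years are excluded
from summaries.

## Synthetic scenes

NDVI follows a double-logistic cycle
$N(d) = w + (m-w)\,[\sigma(a(d-S_y)) - \sigma(b(d-A_y))]$ sampled at the
24 composite midpoints plus Gaussian noise (default SD 0.02 NDVI units,
typical of well-calibrated composite records). The true spring/autumn
inflection days drift linearly (defaults −0.10 and +0.11 d/yr — the
regional magnitudes this kind of analysis reports) with 2-day
interannual jitter, and respond to preseason climate anomalies:
$S_y = S_0 + \tau_S (y - y_0) - \beta_{T}\,\bar T_{pre,y} + \varepsilon$,
and analogously $A_y$ with $+\beta_{T}'\bar T + \beta_P \bar P$.
Couplings default to 3 d/°C (temperature→SOS), 1.5 d/°C and 0.15 d/mm
(temperature/precipitation→EOS) at a 2-month lag — strong enough that a
30-year record detects them, matching the "dominant driver" regime the
attribution is meant to demonstrate. Monthly climate anomalies are white
noise generated on the coarse climate grid and shared by all fine pixels
in a cell (mirroring the 0.5° climate vs ~8 km NDVI structure);
precipitation is truncated at zero and the *effective* (post-truncation)
anomaly is what enters $A_y$ and what the climate cubes contain, so the
couplings are recoverable exactly as generated.

Daily temperature is a sinusoid plus AR(1) noise (φ = 0.75, innovation
SD 2.5 °C). Its mean (10 °C) and amplitude (13 °C) put the frost season
at roughly days 340–55, clear of every class's NDVI cycle: this is a
structural requirement, not realism tuning — the method itself assumes
snow contamination is confined to the non-growing season, and a
generator violating that assumption measures the violation, not the
method. Consequently the daily cube is *not* a plausible Mongolian-
plateau temperature record (winters are far too mild), and it is
statistically independent of the monthly temperature cube — only the
frost rule consumes it. Snow contamination adds a positive spike
(default 0.15 × U(0.5, 1.5)) with probability 0.5 to composites whose
window overlaps a frost run. Land cover is laid out in quadrants
(grassland/shrubland/forest/barren IGBP codes), so class summaries have
known membership; the barren class is parameterised below the 0.1
vegetation threshold and exercises the mask.

What the scenes do **not** emulate: spatial autocorrelation beyond the
climate-cell block structure, clouded/missing composites, sensor
calibration drift, mixed pixels at class boundaries, or realistic
absolute temperatures. Passing tests therefore establish the numerical
correctness and statistical calibration of the pipeline under its own
assumptions, not its skill on any particular satellite archive.

## Problem sizes and tolerances

The test-suite and acceptance scenes use 10×10 pixels × 30 years
(trend recovery; class means averaged over three replicate scenes, which
puts the Monte-Carlo error of a class mean near 0.008 d/yr against the
±0.03 d/yr check) and 20×20 pixels with 4×4 climate cells (attribution),
with 10,000-replicate null simulations for significance calibration —
sizes at which every documented property is measurable with comfortable
margins on a single CPU in seconds. Oracle-equivalence checks
(partial correlation vs residual regression, OLS vs closed form) use
1e-10 tolerances; round-trip I/O uses 1e-6.

## Known limitations

* Grids must nest for resampling/aggregation; there is no reprojection.
* The frost rule needs daily temperature covering every composite
  window; gaps are an error, not an imputation.
* Pixels whose growing season straddles the calendar year boundary
  (southern-hemisphere phenology) are outside the model: SOS < EOS
  within one year is assumed throughout.
* The Polyfit-Mr dates carry a method-specific constant offset relative
  to the generating inflection days; analyses built on trends,
  anomalies or correlations are unaffected, absolute dates are not
  bias-corrected.
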