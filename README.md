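# lspheno

Land-surface phenology from NDVI composite time series: extraction of the
start (SOS), end (EOS) and length (GSL = EOS − SOS) of the growing season
with the **Polyfit-Mr** method, per-pixel linear trend analysis stratified
by land cover, and partial-correlation attribution of SOS/EOS variability
to preseason temperature, precipitation and insolation.

The package is aimed at remote-sensing and ecosystem scientists working
with long gridded vegetation-index records (e.g. ~8 km, 15-day AVHRR
composites over semi-arid steppe) and coarse monthly climate grids
(e.g. 0.5°). Because such archives are large and slow to obtain, a
first-class synthetic-scene generator produces NDVI, daily temperature,
monthly climate and land cover with *known* phenological ground truth and
*known* climate couplings, so every stage of the pipeline is testable end
to end without downloading anything.

## Method

For each vegetated pixel (mean NDVI ≥ 0.1 over the record):

1. **Snow cleaning.** A 15-day composite is treated as potentially
   snow-covered when its window overlaps a run of ≥ 5 consecutive days
   with daily mean temperature < 0 °C; it is replaced by the same pixel's
   NDVI at the temporally nearest snow-free composite.
2. **Climatology fit.** The multi-year mean seasonal cycle
   $\bar{N}(d)$ is fitted with a six-degree polynomial on $t = d/365$
   (linear least squares, refined by Levenberg–Marquardt).
3. **Thresholds.** SOS/EOS climatological dates are the days of maximum
   and minimum rate of change $\bar{N}'(d)$ of the fitted daily curve;
   the fitted NDVI values at those days become the pixel's thresholds.
4. **Per-year dating.** For every year, SOS is the first upward crossing
   of the SOS threshold before the annual maximum and EOS the first
   downward crossing after it, at sub-day resolution; GSL = EOS − SOS.
5. **Trends.** Per-pixel OLS of each metric on year with a two-sided
   slope t-test; class-stratified tables (mean ± SD of significant
   slopes, % area significantly positive/negative at p < 0.05).
6. **Attribution.** SOS/EOS are averaged into the coarse climate cells;
   per cell and climate variable the preseason of 0–5 months ending in
   the mean event month with the highest |Pearson r| is selected
   (temperature averaged, precipitation/insolation summed over the
   window), and the partial correlation of the event with that variable
   is computed controlling for the other two, from the inverse of the
   joint correlation matrix, with $t = r\sqrt{(n-2-k)/(1-r^2)}$.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```python
from lspheno import (SceneConfig, generate_scene, detect_snow, replace_snow,
                     vegetation_mask, extract_phenology, all_trends,
                     reclassify_landcover, summarize_by_class)

scene = generate_scene(SceneConfig(seed=42))     # 10x10 pixels, 1982-2011
snow  = detect_snow(scene.daily_temp, scene.ndvi.times)
clean = replace_snow(scene.ndvi, snow)
pheno = extract_phenology(clean, vegetation_mask(clean))
table = summarize_by_class(all_trends(pheno),
                           reclassify_landcover(scene.landcover))
print(table.head(3).to_string(index=False))
```

prints

```
metric     class  mean_slope  sd_slope  pct_positive  pct_negative  n_valid  n_significant
   sos grassland      -0.149       NaN         0.000         4.000       25              1
   sos shrubland      -0.178     0.028         0.000        16.000       25              4
   sos    forest      -0.138     0.022         0.000        68.000       25             17
```

The scene was generated with a spring advance of −0.10 d/yr plus active
preseason climate couplings; `mean_slope` is the average over pixels
whose trend is significant at p < 0.05 (hence more extreme than the
configured drift — the familiar selection effect of significance-filtered
means), and `pct_negative` is the share of the class's area with a
significantly earlier SOS. The `examples/` scripts walk through each
capability (scene simulation, extraction, trends, attribution) and print
the numbers with interpretation; `lspheno --help` exposes the same
pipeline as shell commands (`simulate`, `preprocess`, `phenology`,
`trends`, `attribute`) reading and writing CF-style NetCDF and CSV.

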