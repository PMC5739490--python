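"""Per-pixel phenology trends stratified by land cover.

Ordinary least squares of SOS/EOS/GSL on year, per pixel, then a
class-stratified table: mean and spread of the significant slopes and the
percentage of each class's area with significant positive/negative
change (p < 0.05) — the standard summary of a regional trend analysis.
"""
from lspheno import (
    SceneConfig, all_trends, area_fraction_significant, detect_snow,
    extract_phenology, generate_scene, reclassify_landcover, replace_snow,
    summarize_by_class, vegetation_mask,
)

scene = generate_scene(SceneConfig(seed=42))
snow = detect_snow(scene.daily_temp, scene.ndvi.times)
clean = replace_snow(scene.ndvi, snow)
veg = vegetation_mask(clean)
pheno = extract_phenology(clean, veg)

landcover = reclassify_landcover(scene.landcover)  # IGBP-17 -> 4 groups
trends = all_trends(pheno)
table = summarize_by_class(trends, landcover)
print(table.to_string(index=False, float_format=lambda v: f"{v:7.3f}"))

pct = area_fraction_significant(trends["sos"], veg.valid, sign="negative")
print(f"\n{pct:.0f}% of the vegetated area shows a significantly earlier "
      "SOS (p < 0.05)")
print("the configured drifts were SOS -0.10, EOS +0.11, hence GSL +0.21 d/yr;")
print("mean significant slopes above should sit near those values")
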