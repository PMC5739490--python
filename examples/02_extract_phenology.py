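"""Clean a composite cube and extract SOS/EOS/GSL with Polyfit-Mr.

Snow-contaminated composites (15-day windows overlapping a >=5-day
sub-zero run) are replaced with the temporally nearest snow-free value,
non-vegetated pixels (mean NDVI < 0.1) are masked, and the growing season
is dated per pixel and year from the rate-of-change thresholds of a
degree-6 polynomial fit to the NDVI climatology.
"""
import numpy as np

from lspheno import (
    SceneConfig, detect_snow, extract_phenology, generate_scene,
    replace_snow, vegetation_mask,
)

scene = generate_scene(SceneConfig(seed=42))

snow = detect_snow(scene.daily_temp, scene.ndvi.times)
clean = replace_snow(scene.ndvi, snow)
veg = vegetation_mask(clean)
pheno = extract_phenology(clean, veg)

print(f"snow-flagged composites: {snow.flags.mean():.0%}")
print(f"vegetated pixels:        {veg.valid.sum()} of {veg.valid.size}")

ok = pheno.ok()
print(f"dated pixel-years:       {ok.sum()} of {ok.size}")
print(f"mean SOS: day {np.nanmean(pheno.sos[ok]):.1f}"
      f"   mean EOS: day {np.nanmean(pheno.eos[ok]):.1f}"
      f"   mean GSL: {np.nanmean(pheno.gsl[ok]):.1f} days")
print("\ntrue grassland spring inflection is day "
      f"{scene.truth.s[:, :5, :5].mean():.1f}; the SOS estimate carries the "
      "constant offset of the rate-of-change threshold definition, which "
      "cancels in trends and correlations")
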