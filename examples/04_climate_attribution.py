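"""Attribute SOS/EOS variability to preseason climate.

Phenology is averaged into the coarse climate cells, the preseason length
(0-5 months before the mean event month) with the strongest correlation
is selected per climate variable, and partial correlations are computed
controlling for the other variables. The generator couples warm
preseasons to earlier springs and warm/wet preseasons to later autumns,
so temperature-SOS should come back negative and precipitation-EOS
positive.
"""
import numpy as np

from lspheno import (
    SceneConfig, aggregate_phenology, attribute, detect_snow,
    extract_phenology, generate_scene, reclassify_landcover, replace_snow,
    resample_majority, summarize_attribution, vegetation_mask,
)
from lspheno.grids import GridSpec

config = SceneConfig(seed=42, grid=GridSpec(20, 20, 0.1, (100.0, 50.0), "scene"))
scene = generate_scene(config)
snow = detect_snow(scene.daily_temp, scene.ndvi.times)
clean = replace_snow(scene.ndvi, snow)
pheno = extract_phenology(clean, vegetation_mask(clean))

cells = aggregate_phenology(pheno, scene.temperature.grid)
results = attribute(cells, {
    "temperature": scene.temperature,
    "precipitation": scene.precipitation,
    "insolation": scene.insolation,
})

for event, variable in [("sos", "temperature"), ("eos", "precipitation"),
                        ("eos", "temperature"), ("sos", "insolation")]:
    sub = results[(results.event == event) & (results.variable == variable)]
    sub = sub[np.isfinite(sub.partial_r)]
    sig = sub[sub.p_value < 0.05]
    print(f"{event.upper()} ~ {variable:13s} median partial r "
          f"{sub.partial_r.median():+.2f}, significant in {len(sig)}/{len(sub)} "
          f"cells, modal lag {int(sub.lag.mode()[0])} months")

coarse_lc = resample_majority(reclassify_landcover(scene.landcover),
                              scene.temperature.grid)
table = summarize_attribution(results, coarse_lc)
veg = table[(table.n_cells > 0) & (table.variable != "sos")]
print("\nper-class percentages of significantly correlated cells:")
print(veg.to_string(index=False, float_format=lambda v: f"{v:6.1f}"))
print("\nthe generating couplings were: temperature->SOS negative, "
      "temperature- and precipitation->EOS positive, insolation uncoupled, "
      "all at a 2-month preseason lag")
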