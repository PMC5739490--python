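"""Land-cover reclassification and resolution matching.

The 17 IGBP classes are grouped into four categories for stratified
summaries: grassland (grassland + savanna classes), shrubland (closed and
open shrubland), forest (needleleaf, deciduous broadleaf and mixed forest),
and "other" for everything else (barren, wetlands, built-up, croplands,
water, snow/ice). Woody savanna is, by default, treated as part of the
grassland group (it is a savanna subclass); this is configurable.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import (
    FOREST,
    GRASSLAND,
    GROUPED4,
    IGBP17,
    OTHER,
    SHRUBLAND,
    GridSpec,
    LandCoverMap,
)

_FOREST_CODES = {1, 3, 4, 5}  # evergreen/deciduous needleleaf, decid. broadleaf, mixed
_SHRUB_CODES = {6, 7}
_GRASS_CODES = {9, 10}  # savanna, grassland
_WOODY_SAVANNA = 8


def grouping_table(woody_savanna_as_grassland: bool = True) -> pd.DataFrame:
    """IGBP-code -> grouped-code correspondence as a tidy table."""
    rows = []
    for code, name in IGBP17.items():
        if code in _FOREST_CODES:
            grouped = FOREST
        elif code in _SHRUB_CODES:
            grouped = SHRUBLAND
        elif code in _GRASS_CODES or (
            code == _WOODY_SAVANNA and woody_savanna_as_grassland
        ):
            grouped = GRASSLAND
        else:
            grouped = OTHER
        rows.append((code, name, grouped, GROUPED4[grouped]))
    return pd.DataFrame(
        rows, columns=["igbp_code", "igbp_name", "grouped_code", "grouped_name"]
    )


def reclassify_landcover(
    lc: LandCoverMap, woody_savanna_as_grassland: bool = True
) -> LandCoverMap:
    """Collapse an IGBP-17 map into the four grouped categories.

    Idempotent on grouped-4 inputs. Unknown codes raise with the offending
    values listed.
    """
    if lc.scheme == "grouped-4":
        return LandCoverMap(lc.codes.copy(), lc.grid, "grouped-4")
    if lc.scheme != "IGBP-17":
        raise ValueError(f"cannot reclassify scheme {lc.scheme!r}")
    table = grouping_table(woody_savanna_as_grassland)
    lut = np.full(max(IGBP17) + 1, -1, dtype=np.int64)
    lut[table["igbp_code"].to_numpy()] = table["grouped_code"].to_numpy()
    codes = lc.codes
    bad = sorted(set(codes.ravel()) - set(IGBP17))
    if bad:
        raise ValueError(f"unknown IGBP codes: {bad}")
    return LandCoverMap(lut[codes], lc.grid, "grouped-4")


def resample_majority(lc: LandCoverMap, target: GridSpec) -> LandCoverMap:
    """Assign each coarse cell the modal class of the fine cells it covers.

    Requires the target grid to nest in the source grid (integer cell-size
    multiple, shared origin and extent). Ties are broken toward the lowest
    class code, which for grouped maps means grassland < shrubland < forest
    < other — deterministic and reproducible.
    """
    factor = lc.grid.nesting_factor(target)
    codes = lc.codes
    blocks = codes.reshape(target.n_rows, factor, target.n_cols, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(
        target.n_rows, target.n_cols, factor * factor
    )
    out = np.empty((target.n_rows, target.n_cols), dtype=np.int64)
    for i in range(target.n_rows):
        for j in range(target.n_cols):
            counts = np.bincount(blocks[i, j])
            out[i, j] = counts.argmax()  # argmax takes the lowest code on ties
    return LandCoverMap(out, target, lc.scheme)
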