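import numpy as np
import pytest

from lspheno import (
    SceneConfig,
    detect_snow,
    extract_phenology,
    generate_scene,
    replace_snow,
    vegetation_mask,
)
from lspheno.grids import GridSpec


@pytest.fixture(scope="session")
def trendy_scene():
    """Default-grid scene with trends but no climate couplings."""
    return generate_scene(
        SceneConfig(seed=7, beta_t_sos=0.0, beta_t_eos=0.0, beta_p_eos=0.0)
    )


@pytest.fixture(scope="session")
def trendy_pipeline(trendy_scene):
    """(scene, cleaned cube, vegetation mask, phenology) for the trendy scene."""
    scene = trendy_scene
    snow = detect_snow(scene.daily_temp, scene.ndvi.times)
    clean = replace_snow(scene.ndvi, snow)
    veg = vegetation_mask(clean)
    pheno = extract_phenology(clean, veg)
    return scene, clean, veg, pheno


@pytest.fixture(scope="session")
def coupled_scene():
    """Larger scene with active preseason climate couplings (16 coarse cells)."""
    return generate_scene(
        SceneConfig(seed=11, grid=GridSpec(20, 20, 0.1, (100.0, 50.0), "scene"))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
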