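import numpy as np
import pytest

from coilwatch import default_scenario, make_subject


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small recurrence phantom: 64-voxel grid, 3 mm sac, 18% programmed
    growth, 1 mm coil translation."""
    return default_scenario(
        sac_radius_mm=3.0,
        growth_fraction=0.18,
        coil_center_offset_mm=(0.7, 0.5, 0.5),
        cohort="recurrence",
        seed=11,
        grid_shape=(64, 64, 64),
        coil_fill_fraction=0.3,
    )


@pytest.fixture(scope="session")
def tiny_subject(tiny_scenario):
    """Rasterized images and completed ground truth for the tiny phantom."""
    return make_subject(tiny_scenario)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150420)
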