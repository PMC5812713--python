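import numpy as np
import pytest

from normsupp import normalization_model as nm


@pytest.fixture
def params() -> nm.ModelParams:
    return nm.ModelParams()


@pytest.fixture
def grid(params) -> nm.SpatialGrid:
    return nm.SpatialGrid.for_stimuli(12.0, params)


@pytest.fixture
def small_grid() -> nm.SpatialGrid:
    """Coarse grid of < 200 cells for brute-force convolution oracles.

    The 0.125 deg spacing is exactly representable, so kernel
    truncation boundaries are float-noise free.
    """
    positions = np.arange(-79, 80) * 0.125
    features = np.arange(0.0, 360.0, 45.0)
    return nm.SpatialGrid(positions=positions, features=features)
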