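import logging

import numpy as np
import pytest

from neuromorph import GeneratorParams, Image2D

logging.getLogger("neuromorph").setLevel(logging.ERROR)

# Small-field parameters for fast pipeline tests: 53 um field (256 px grid),
# same calibration and nucleus sizes as the full-field defaults.
SMALL_FIELD = dict(field_size_um=53.0, n_cells=3, neurites_per_cell_range=(1, 2))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    return GeneratorParams(noise_model="none", seed=11, **SMALL_FIELD)


def make_image(values, pixel_size_um=0.207):
    return Image2D(np.asarray(values), pixel_size_um)


@pytest.fixture
def two_valued_image():
    vals = np.full((16, 16), 20, dtype=np.uint8)
    vals[:, 8:] = 220
    return make_image(vals)
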