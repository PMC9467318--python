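import numpy as np
import pytest

from tmtgaze import (
    PAPER_GEOMETRY,
    DetectionParams,
    LayoutConfig,
    generate_layout,
)


@pytest.fixture(scope="session")
def geom():
    return PAPER_GEOMETRY


@pytest.fixture(scope="session")
def det_params():
    return DetectionParams()


@pytest.fixture(scope="session")
def layout_a(geom):
    return generate_layout("A", LayoutConfig(geom=geom), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
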