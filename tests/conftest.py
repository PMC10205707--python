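import logging

import numpy as np
import pytest

from vasculong.synthetic import NetworkSpec, make_capillary_bed, make_honeycomb

logging.getLogger("vasculong").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def hexagon():
    """The smallest honeycomb: a single hexagon (6 vessels)."""
    return make_honeycomb(6)


@pytest.fixture(scope="session")
def small_bed():
    """A 3D capillary bed of ~60 vessels with 2 penetrating vessels."""
    return make_capillary_bed(NetworkSpec(target_vessel_count=60,
                                          n_penetrating=2, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
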