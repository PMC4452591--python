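import numpy as np
import pytest

import reefhab as rh


@pytest.fixture(scope="session")
def default_world():
    """Reference synthetic world at the default study conditions."""
    return rh.generate_world(rh.WorldConfig(seed=11))


@pytest.fixture(scope="session")
def default_obs(default_world):
    w = default_world
    return rh.rasterize_reefs(w.reefs, w.env.fine_spec, w.env.coarse_spec)


@pytest.fixture(scope="session")
def small_world():
    """2° x 3° world, small enough for literal brute-force oracles."""
    cfg = rh.WorldConfig(
        lat_min=0.0, lat_max=2.0, lon_min=0.0, lon_max=3.0, seed=5, n_marginal=0, n_edge=1
    )
    return rh.generate_world(cfg)


@pytest.fixture(scope="session")
def clean_world():
    """World with neither omitted nor spuriously placed reefs."""
    cfg = rh.WorldConfig(
        lat_min=0.0,
        lat_max=4.0,
        lon_min=0.0,
        lon_max=10.0,
        seed=3,
        omission_rate=0.0,
        commission_rate=0.0,
    )
    return rh.generate_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
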