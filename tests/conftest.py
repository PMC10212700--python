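import numpy as np
import pytest

import ecogeo as eg


@pytest.fixture(scope="session")
def env_small():
    """60x60 synthetic landscape shared across tests (uncorrelated layers)."""
    spec = eg.LandscapeSpec(n_rows=60, n_cols=60, seed=7)
    return eg.gen_env_stack(spec)


@pytest.fixture(scope="session")
def specialist():
    """A narrow Gaussian-bell species on the temperature axis."""
    return eg.VirtualSpecies("specialist", {"bio1": 6.0}, {"bio1": 1.0})


@pytest.fixture(scope="session")
def background_small(env_small):
    return eg.sample_background(env_small, 1500, seed=99)


@pytest.fixture()
def tiny_env():
    """Deterministic 4x5 stack with a simple gradient and one masked cell."""
    lon = np.arange(5)[None, :].repeat(4, axis=0).astype(float)
    lat = np.arange(4)[:, None].repeat(5, axis=1).astype(float)
    mask = np.ones((4, 5), dtype=bool)
    mask[1, 2] = False
    return eg.EnvStack({"bio1": lon + 1.0, "bio12": 10 * lat + 5.0},
                       mask, eg.GridTransform(100.0, 30.0, 0.5))
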