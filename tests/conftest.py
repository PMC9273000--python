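import numpy as np
import pytest

from nanostoich import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A fast single-cell phantom: 96×96 px over a 36 μm field."""
    return PhantomConfig(grid=(96, 96), pixel_size=36.0 / 96, n_cells=1,
                         n_aggregates=4, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config)


@pytest.fixture(scope="session")
def series_config() -> PhantomConfig:
    """Three-cell phantom at 256×256, the exposure-series study scale."""
    return PhantomConfig(grid=(256, 256), pixel_size=36.0 / 256, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240615)
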