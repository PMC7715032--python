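import numpy as np
import pytest

from ca3net.geometry import PopulationConfig, build_layout


@pytest.fixture(scope="session")
def small_layout():
    """A light three-population layout reused across tests."""
    sizes = {"EC": 200, "DG": 300, "CA3": 150}
    return build_layout(PopulationConfig(sizes=sizes), seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
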