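import numpy as np
import pytest

from reweave.builder import classify_regions, place_neurons, wire_initial


@pytest.fixture(scope="session")
def small_layout():
    return place_neurons(0.05, seed=7)  # 400 E + 100 I


@pytest.fixture(scope="session")
def small_regions(small_layout):
    return classify_regions(small_layout)


@pytest.fixture(scope="session")
def small_connectome(small_layout):
    return wire_initial(small_layout, 0.02, g_unit=2.0, g_sigma=0.4, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
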