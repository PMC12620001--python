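import numpy as np
import pytest

from softbreed import (
    SchemeConfig,
    build_marker_map,
    sample_trait,
    simulate_founders,
)


@pytest.fixture(scope="session")
def tiny_map():
    """12 markers on two chromosomes, 10 cM spacing."""
    return build_marker_map([6, 6], spacing_cM=10.0)


@pytest.fixture(scope="session")
def tiny_founders(tiny_map):
    return simulate_founders(tiny_map, 20, seed=11)


@pytest.fixture(scope="session")
def tiny_trait(tiny_map):
    return sample_trait(tiny_map, seed=12)


@pytest.fixture()
def tiny_config():
    return SchemeConfig(
        generations=2, top_k=5, selection="SI1", n_selected=5, temperature=0.5
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2029)
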