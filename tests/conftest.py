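import numpy as np
import pytest

from palmbreed.scheme import SchemeConfig, initial_state


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Reduced desk configuration used by cross-module integration tests."""
    return SchemeConfig(
        scheme="RRS",
        n_cycles=1,
        n_loci=600,
        n_markers=250,
        n_qtl_per_trait=100,
    )


@pytest.fixture(scope="session")
def small_state(small_config):
    """One deterministic generation-0 state shared across read-only tests."""
    return initial_state(small_config, np.random.default_rng(777))


@pytest.fixture
def small_state_copy(small_state):
    return small_state.clone()
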