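import numpy as np
import pytest

from varscale.core import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A scenario small enough for fast unit tests."""
    return ScenarioConfig(
        cv=0.15, h2=0.25, mu=100.0, r=1.0, n_individuals=5000, n_replicates=3, seed=11
    )
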