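import numpy as np
import pytest

from dunecast import AnnualSeries, WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic world shared across read-only tests."""
    return generate_world(WorldConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_series(values, start=2000, **kw) -> AnnualSeries:
    values = np.asarray(values, dtype=float)
    return AnnualSeries(np.arange(start, start + values.size), values, **kw)
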