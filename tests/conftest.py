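import pytest

from flavoet import ETParameters, TrajectorySpec, default_generator_params


@pytest.fixture
def params() -> ETParameters:
    """Core placeholder parameter set (nonadiabatic gate inside the Rc window)."""
    return ETParameters()


@pytest.fixture
def gen_params() -> ETParameters:
    """Ultrafast-donor generator parameter set (gate saturated)."""
    return default_generator_params()


@pytest.fixture
def fast_spec() -> TrajectorySpec:
    """Small, quick synthetic trajectory spec."""
    return TrajectorySpec(seed=123, n_snapshots=200)
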