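import pytest

from hostquant import RunConfig, SimulationConfig


@pytest.fixture
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def clean_cfg() -> SimulationConfig:
    """Amplitude model without rain or false positives: calling is exact."""
    return SimulationConfig(rain_fraction=0.0, false_positive_rate=0.0)
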