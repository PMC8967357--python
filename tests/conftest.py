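import pytest

from alliumsim import SimulationConfig, run_season, synthesize_weather


@pytest.fixture(scope="session")
def subtropical_weather():
    return synthesize_weather("subtropical", years=2, seed=3)


@pytest.fixture(scope="session")
def continental_weather():
    return synthesize_weather("continental", years=2, seed=3)


@pytest.fixture(scope="session")
def rue_config():
    return SimulationConfig(carbon_source="rue")


@pytest.fixture(scope="session")
def subtropical_season(rue_config, subtropical_weather):
    return run_season(rue_config, subtropical_weather)


@pytest.fixture(scope="session")
def continental_season(rue_config, continental_weather):
    return run_season(rue_config, continental_weather)
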