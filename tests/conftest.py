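import datetime as dt

import pytest

from topdress import synthetic as syn
from topdress.crop_model import CultivarParams, get_model, simulate_season


@pytest.fixture(scope="session")
def weather():
    """Standard seeded season: early-October start, 275 days."""
    return syn.generate_weather(dt.date(2020, 10, 2), 275, seed=3)


@pytest.fixture(scope="session")
def soil():
    return syn.default_soil()


@pytest.fixture(scope="session")
def sowing_date():
    return dt.date(2020, 10, 5)


@pytest.fixture(scope="session")
def mgmt(sowing_date):
    return syn.default_management(sowing_date, 180.0)


@pytest.fixture(scope="session")
def model():
    return get_model()


@pytest.fixture(scope="session")
def truth_sim(weather, soil, mgmt):
    return simulate_season(weather, soil, mgmt, CultivarParams())


@pytest.fixture(scope="session")
def noiseless_experiment():
    return syn.generate_experiment(noise=syn.NoiseModel.noiseless(), seed=11)
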