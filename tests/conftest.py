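import logging

import numpy as np
import pytest

from antshift import climate, synth

logging.getLogger("antshift").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def flat_grid():
    return climate.ClimateGrid(values=np.full((8, 8), 9.5), cell_size=30.0)


@pytest.fixture()
def random_grid(rng):
    return climate.ClimateGrid(values=rng.normal(10.0, 2.0, (10, 10)), cell_size=30.0)


@pytest.fixture(scope="session")
def default_study():
    """One survey-design synthetic study shared across tests."""
    return synth.make_study(synth.SyntheticStudyConfig(seed=11))


@pytest.fixture(scope="session")
def site_temps(default_study):
    return default_study.site_temps
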