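import numpy as np
import pytest

from lakeflux import ScenarioConfig, run_loading_scenario
from lakeflux.synthetic_data import end_member_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def end_members():
    return end_member_profiles()


@pytest.fixture(scope="session")
def default_scenario():
    """One shared run of the loading scenario at the default conditions."""
    return run_loading_scenario(ScenarioConfig(seed=0))
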