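import pytest

from oxyquant import synth
from oxyquant.domain import default_assumptions, default_facility_type_params


@pytest.fixture(scope="session")
def assumptions():
    return default_assumptions()


@pytest.fixture(scope="session")
def type_params():
    return default_facility_type_params()


@pytest.fixture(scope="session")
def gen_config():
    return synth.GeneratorConfig(seed=20230901)


@pytest.fixture(scope="session")
def roster(gen_config):
    return synth.generate_inventories(synth.generate_roster(gen_config), gen_config)


@pytest.fixture(scope="session")
def report_panel(roster, gen_config):
    # 99 facilities x 6 months = 594 facility-months, enough for
    # parameter-recovery checks at binomial precision.
    return synth.generate_reports(roster, gen_config, months=6)
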