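import pytest

import vaxprice as v


@pytest.fixture
def baseline() -> v.Scenario:
    """Pinned reference calibration: positive income gap, exclude-deceased kernel."""
    return v.scenario_from_config(v.preset("baseline"))


@pytest.fixture
def knife_edge() -> v.Scenario:
    """Zero income gap and no mortality: vaccination cannot move the price."""
    return v.scenario_from_config(v.preset("zero-gap-no-mortality"))


@pytest.fixture
def disease_free() -> v.Scenario:
    """No infected, no vaccination: the constant-dividend Lucas closed form applies."""
    return v.scenario_from_config(v.preset("disease-free"))


@pytest.fixture
def infected_excluded() -> v.Scenario:
    """Infected shut out of markets: consumption pinned at the floor."""
    return v.scenario_from_config(v.preset("infected-excluded"))
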