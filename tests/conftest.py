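import pytest
from hypothesis import HealthCheck, settings

import oacost as oc

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture(scope="session")
def ctx() -> oc.ValuationContext:
    return oc.load_valuation_context(oc.bundled_path("valuation"))


@pytest.fixture(scope="session")
def boa() -> oc.CareModelSpec:
    return oc.load_care_model(oc.bundled_path("boa"))


@pytest.fixture(scope="session")
def ja() -> oc.CareModelSpec:
    return oc.load_care_model(oc.bundled_path("ja"))
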