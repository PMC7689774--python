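import pytest

from f19lung import presets


@pytest.fixture(scope="session")
def gases():
    return presets.load_gases()


@pytest.fixture(scope="session")
def protocols():
    return presets.load_protocols()


@pytest.fixture(scope="session")
def ofcb_invivo(gases):
    return gases["ofcb-invivo"]


@pytest.fixture(scope="session")
def pfp_invivo(gases):
    return gases["pfp-invivo"]
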