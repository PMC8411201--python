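import pytest

import sustainflux as sf


@pytest.fixture(scope="session")
def toys():
    return sf.make_toy_models()


@pytest.fixture
def toy_a(toys):
    return toys["TOY-A"].copy()


@pytest.fixture
def toy_a2(toys):
    return toys["TOY-A2"].copy()


@pytest.fixture
def toy_b(toys):
    return toys["TOY-B"].copy()


@pytest.fixture
def econ_table():
    return sf.canonical_economic_table()


@pytest.fixture
def econ_weights():
    return sf.canonical_economic_weights()
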