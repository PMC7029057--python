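import pytest
from hypothesis import settings

from leafopt.params import default_params

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def params():
    return default_params()


@pytest.fixture
def traits(params):
    return params.traits


@pytest.fixture
def env(params):
    return params.env
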