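import pytest
from hypothesis import settings

from magnetea import analyze, builtin_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def base_single():
    return builtin_fixture("base_single")


@pytest.fixture()
def base_semi():
    return builtin_fixture("base_semicontinuous")


@pytest.fixture(scope="session")
def result_single():
    return analyze(builtin_fixture("base_single"))


@pytest.fixture(scope="session")
def result_semi():
    return analyze(builtin_fixture("base_semicontinuous"))
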