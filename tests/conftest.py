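import pytest
from hypothesis import settings

from plsedit import fixtures

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from plsedit.target_matching import match_profile


@pytest.fixture(scope="session")
def ppr65():
    return fixtures.ppr65_array()


@pytest.fixture(scope="session")
def native_window():
    return fixtures.ppr65_native_window()


@pytest.fixture(scope="session")
def native_profile(ppr65, native_window):
    return match_profile(ppr65, native_window)


@pytest.fixture(scope="session")
def offtarget_windows():
    return fixtures.ppr65_offtarget_windows()
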