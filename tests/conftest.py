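import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rulemap.fixtures import (  # noqa: E402
    decay_fixture, dimer_fixture, lyn_fixture, two_group_fixture,
)


@pytest.fixture(scope="session")
def lyn_correct():
    return lyn_fixture(True)


@pytest.fixture(scope="session")
def lyn_incorrect():
    return lyn_fixture(False)


@pytest.fixture(scope="session")
def dimer_model():
    return dimer_fixture()


@pytest.fixture(scope="session")
def decay_model():
    return decay_fixture(k=0.7, a0=1000.0)


@pytest.fixture(scope="session")
def two_group_model():
    return two_group_fixture()
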