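from pathlib import Path

import pytest

import fcmdap

FIXTURE_DIR = Path(__file__).parent / "data" / "toy10"


@pytest.fixture(scope="session")
def toy():
    """The fixed ten-interaction worked-example bundle."""
    return fcmdap.toy10_fixture()


@pytest.fixture(scope="session")
def toy_results(toy):
    return fcmdap.FCMDAP.from_bundle(toy).fit()


@pytest.fixture(scope="session")
def planted():
    """Default planted-signal bundle at the reference seed."""
    return fcmdap.generate(7)


@pytest.fixture(scope="session")
def planted_results(planted):
    return fcmdap.FCMDAP.from_bundle(planted).fit()
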