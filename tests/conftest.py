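import pytest

from sipflux import IncubationSetup, build_paper_fixtures


@pytest.fixture(scope="session")
def setup():
    return IncubationSetup()


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic fixture bundle anchored to the published summary values."""
    return build_paper_fixtures()
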