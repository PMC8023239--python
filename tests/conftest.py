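import logging

import pytest

from viromefmt import SimParams, simulate_study, write_fixtures

logging.getLogger("viromefmt").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (paper-scale design, desk-scale catalog)."""
    return simulate_study(SimParams(seed=7))


@pytest.fixture(scope="session")
def fixture_dir(default_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    write_fixtures(default_study, out)
    return out
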