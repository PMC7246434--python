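import pytest

from pocus_impact import (
    EmissionFactorTable,
    default_osona_profile,
    generate_register,
)


@pytest.fixture(scope="session")
def osona_profile():
    return default_osona_profile()


@pytest.fixture(scope="session")
def osona_data(osona_profile):
    """(register, centres) for the packaged study profile, seed 1."""
    return generate_register(osona_profile, seed=1)


@pytest.fixture(scope="session")
def osona_register(osona_data):
    return osona_data[0]


@pytest.fixture(scope="session")
def osona_centres(osona_data):
    return osona_data[1]


@pytest.fixture(scope="session")
def factors():
    return EmissionFactorTable.default()
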