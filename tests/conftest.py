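import pytest

from caremap import (
    GeneratorProfile,
    example_duals,
    example_portraits,
    generate_population,
    load_mapping_matrix,
    load_registry,
)


@pytest.fixture(scope="session")
def ind_reg():
    return load_registry("individual_v1")


@pytest.fixture(scope="session")
def fam_reg():
    return load_registry("family_v1")


@pytest.fixture(scope="session")
def ind_matrix(ind_reg):
    return load_mapping_matrix("individual_demo", ind_reg)


@pytest.fixture(scope="session")
def fam_matrix(fam_reg):
    return load_mapping_matrix("family_v1", fam_reg)


@pytest.fixture(scope="session")
def examples():
    return example_portraits()


@pytest.fixture(scope="session")
def duals():
    return example_duals()


@pytest.fixture(scope="session")
def population20():
    """Small synthetic community used as the CF population in tests."""
    return generate_population(GeneratorProfile(n=20, seed=7))
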