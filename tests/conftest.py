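import numpy as np
import pytest

from menurec.catalog import generate_catalog
from menurec.population import load_demographic_spec, load_group_specs
from menurec.profiles import ProfileGenerator


@pytest.fixture(scope="session")
def generator() -> ProfileGenerator:
    return ProfileGenerator()


@pytest.fixture(scope="session")
def demographic():
    return load_demographic_spec()


@pytest.fixture(scope="session")
def group_specs():
    return {g.name: g for g in load_group_specs()}


@pytest.fixture(scope="session")
def catalog():
    return generate_catalog(rng=np.random.default_rng(1234))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
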