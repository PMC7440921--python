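import numpy as np
import pytest

from ecoscaffold import (
    ANCESTRAL_BLUE,
    ANCESTRAL_RED,
    DERIVED_BLUE,
    DERIVED_RED,
    GrowthFunctionSpec,
    TraitVector,
)


@pytest.fixture(scope="session")
def ancestral_red():
    return ANCESTRAL_RED


@pytest.fixture(scope="session")
def ancestral_blue():
    return ANCESTRAL_BLUE


@pytest.fixture(scope="session")
def ancestral_theta():
    return TraitVector.from_types(ANCESTRAL_RED, ANCESTRAL_BLUE)


@pytest.fixture(scope="session")
def ancestral_spec(ancestral_theta):
    """Standard growth-function spec: ancestral traits, B=15, T=1."""
    return GrowthFunctionSpec(theta=ancestral_theta, B=15, T=1.0)


@pytest.fixture(scope="session")
def derived_theta():
    return TraitVector.from_types(DERIVED_RED, DERIVED_BLUE)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
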