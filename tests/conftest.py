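import numpy as np
import pytest

from vesselseg import SyntheticConfig, fixture_suite, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def suite():
    """The standard six-case synthetic battery (seed fixed for the suite)."""
    return {case.name: case for case in fixture_suite(1)}


@pytest.fixture(scope="session")
def mixed_case(suite):
    return suite["mixed"]


@pytest.fixture(scope="session")
def small_case():
    """A light 128-px case for unit tests that need a realistic image."""
    return generate_case(SyntheticConfig(size=128, seed=11, n_vessels=5,
                                         width_range=(2, 6)), "small")
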