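import numpy as np
import pytest

from copasym import reference, simulate


@pytest.fixture(scope="session")
def census():
    return reference.make_census()


@pytest.fixture(scope="session")
def default_sim():
    """One full multi-species simulation at the built-in study conditions."""
    return simulate(reference.default_specs(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
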