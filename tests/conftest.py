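import numpy as np
import pytest
from hypothesis import settings

import trflp

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pattern_table():
    """Bundled 25-OTU dual-enzyme affiliation table."""
    return trflp.load_reference_patterns()


@pytest.fixture(scope="session")
def chem_table():
    """Bundled 12-sample volatile-oil / galangin summary table."""
    return trflp.load_reference_chemistry()


@pytest.fixture(scope="session")
def design():
    """Bundled 12-sample synthetic study design, seed 0."""
    return trflp.make_reference_design(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
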