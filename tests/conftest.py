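import numpy as np
import pytest

from connfroi.synth import CohortConfig, generate_cohort

#: small-but-complete cohort configuration used across module tests
TINY = CohortConfig(n_subjects=4, n_vertices=320, searchspace_size=12, seed=11)


@pytest.fixture(scope="session")
def tiny_cfg() -> CohortConfig:
    return TINY


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(TINY)


@pytest.fixture(scope="session")
def tiny_surface(tiny_cohort):
    return tiny_cohort.surface


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
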