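import numpy as np
import pytest

from mitostereo import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_cohort():
    """18 interphase cells, the serial-section cohort size."""
    return generate_cohort(CohortConfig(n_cells=18, seed=101))


@pytest.fixture(scope="session")
def medium_cohort():
    return generate_cohort(CohortConfig(n_cells=100, seed=202))
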