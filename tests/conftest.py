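import numpy as np
import pytest

import thermopain as tp


@pytest.fixture(scope="session")
def planted_cohort():
    """A small synthetic cohort with planted structure, shared across tests."""
    spec = tp.CohortSpec(seed=1234)
    table, labels, matrix = tp.generate_cohort(spec)
    return spec, table, labels, matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
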