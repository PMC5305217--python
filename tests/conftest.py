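import numpy as np
import pandas as pd
import pytest

from prismor.cohort import CohortSpec, assign_outcomes, generate_cohort


@pytest.fixture(scope="session")
def cohort_1408():
    """Default-size synthetic cohort with outcomes from the reference model."""
    spec = CohortSpec(n_patients=1408, seed=42)
    return assign_outcomes(generate_cohort(spec), seed=43)


@pytest.fixture(scope="session")
def cohort_large():
    """Larger cohort for asymptotic checks (shared across tests)."""
    spec = CohortSpec(n_patients=20000, seed=7)
    return assign_outcomes(generate_cohort(spec), seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
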