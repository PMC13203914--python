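import numpy as np
import pandas as pd
import pytest

from cryosperm import FeatureTable, SyntheticConfig, generate_cohort, null_cohort


@pytest.fixture(scope="session")
def default_cohort() -> FeatureTable:
    """One default-profile cohort: 10 donors x 7 treatments x 3 replicates."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort() -> FeatureTable:
    """Small cohort for fast I/O and plumbing tests (2 donors, 1 replicate)."""
    return generate_cohort(SyntheticConfig(n_donors=2, replicates=1, seed=3))


@pytest.fixture(scope="session")
def noise_cohort() -> FeatureTable:
    """Cohort whose labels carry no information."""
    return null_cohort(SyntheticConfig(seed=5))
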