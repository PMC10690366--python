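import numpy as np
import pandas as pd
import pytest

from hipscore import CohortConfig, generate_cohort, generate_scores


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=42)


@pytest.fixture(scope="session")
def cohort(default_config) -> pd.DataFrame:
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def scores(cohort, default_config) -> pd.DataFrame:
    return generate_scores(cohort, default_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
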