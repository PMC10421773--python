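import numpy as np
import pandas as pd
import pytest

from molarage import SyntheticConfig, generate_cohort
from molarage.synth import fig4_replica_config


@pytest.fixture(scope="session")
def replica_cohort() -> pd.DataFrame:
    """Cohort mimicking the printed per-tooth sample sizes."""
    return generate_cohort(fig4_replica_config(42), 42)


@pytest.fixture(scope="session")
def large_cohort() -> pd.DataFrame:
    """n=500 per sex, no missingness, default calibration."""
    return generate_cohort(SyntheticConfig(n_f=500, n_m=500, seed=9), 9)


@pytest.fixture()
def tiny_responses() -> pd.DataFrame:
    """Fixed 10-row response fixture for likelihood/WLS oracles."""
    rng = np.random.default_rng(123)
    age = np.array([14.2, 15.1, 16.4, 17.0, 18.3, 19.5, 20.1, 21.6, 22.8, 23.9])
    sex = np.array(["F", "M", "F", "M", "F", "M", "F", "M", "F", "M"])
    y = -1.6 - 0.05 * age + 0.1 * (sex == "M") + rng.normal(0, 0.2, 10)
    return pd.DataFrame({"sex": sex, "age": age, "response": y})
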