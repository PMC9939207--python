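import numpy as np
import pytest

from survscore.derive import add_derived_columns
from survscore.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate simulated cohort with the default configuration."""
    return generate_cohort(SimConfig(n_subjects=1500, seed=42))


@pytest.fixture(scope="session")
def derived_cohort(default_cohort):
    df = add_derived_columns(default_cohort)
    df = df.copy()
    df["male"] = (df["sex"] == "male").astype(int)
    df["smoke"] = (df["smoking"] == "ever").astype(int)
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
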