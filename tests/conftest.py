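import numpy as np
import pytest

from hrindex import load_table1, measured_arm_config, predicted_arm_config
from hrindex.simulate import generate_cohort


@pytest.fixture(scope="session")
def table1():
    """The packaged 40-study descriptive table."""
    return load_table1()


@pytest.fixture(scope="session")
def null_cohort():
    """Measured-arm synthetic cohort with no systematic bias."""
    return generate_cohort(measured_arm_config(seed=11))


@pytest.fixture(scope="session")
def biased_cohort():
    """Predicted-arm synthetic cohort carrying the default 21.1% bias."""
    return generate_cohort(predicted_arm_config(seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(2016)
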