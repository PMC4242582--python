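import numpy as np
import pandas as pd
import pytest

from limosa.simulate import Scenario, generate


@pytest.fixture(scope="session")
def rp_dataset():
    """One full synthetic study under resource partitioning, fixed seed."""
    return generate(Scenario(hypothesis="resource_partitioning", seed=1))


@pytest.fixture(scope="session")
def null_scenario():
    return Scenario(hypothesis="null", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def three_sessions():
    """Worked sex-ratio example: 60, 70, 80 females out of 100."""
    return pd.DataFrame(
        {
            "site": ["A"] * 3,
            "session_id": ["s1", "s2", "s3"],
            "n_male": [40, 30, 20],
            "n_female": [60, 70, 80],
        }
    )
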