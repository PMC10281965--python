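import numpy as np
import pytest

from pentrace.features import feature_table
from pentrace.simulate import default_group_params, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default two-group study cohort (66 non-CM / 38 CM, seed 42)."""
    return simulate_cohort(default_group_params("nonCM"),
                           default_group_params("CM"), seed=42)


@pytest.fixture(scope="session")
def default_features(default_cohort):
    """Feature table of the default cohort (one row per recording)."""
    return feature_table(default_cohort.recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
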