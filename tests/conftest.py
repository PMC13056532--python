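import numpy as np
import pandas as pd
import pytest

from maihda import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default additive cohort, 4000 per sex."""
    return generate_cohort(SyntheticConfig(n_per_sex=4000, seed=11))


@pytest.fixture(scope="session")
def toy_linear():
    """Balanced one-way toy with closed-form ANOVA solution."""
    y = np.array([1.0, 3.0, 5.0, 7.0])
    X = pd.DataFrame({"intercept": np.ones(4)})
    groups = np.array(["00000", "00001", "00000", "00001"])[[0, 0, 1, 1]]
    return y, X, groups
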