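import numpy as np
import pytest

import mcqcpm as mc

COVARIATE_COLS = ["age", "gender", "motion"]


def covmat(behavior_df):
    """Covariate matrix (age, gender, head motion) from a behavior table."""
    return behavior_df[COVARIATE_COLS].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted cohort: n=180, 60 nodes, 50 positive CSC edges at r=0.5."""
    return mc.generate_cohort(mc.default_planted_config(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted cohort for fast unit tests (n=60, 20 nodes, 10 edges)."""
    cfg = mc.default_planted_config(seed=1, n_subjects=60, n_nodes=20, n_planted=10)
    return mc.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
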