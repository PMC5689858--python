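import numpy as np
import pytest

import protonmu as pm


@pytest.fixture(scope="session")
def catalog():
    return pm.default_catalog()


@pytest.fixture(scope="session")
def published():
    """The published commissioning-table excerpts (ROF / RSF / FSF)."""
    return pm.load_published_tables()


@pytest.fixture(scope="session")
def truth():
    return pm.TruthMachine.default()


@pytest.fixture(scope="session")
def noise_free_study():
    """Full noise-free pipeline: campaign, tables, fits, validation diffs."""
    truth = pm.TruthMachine.default(sigma=0.0)
    return pm.validation_study(truth, seed=1, sigma=0.0)


@pytest.fixture(scope="session")
def noise_free_tables(noise_free_study):
    return noise_free_study["tables"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
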