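import numpy as np
import pytest

from pcnslkit import synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the replication conditions (41 F / 33 M, planted clusters)."""
    return synthetic.generate_cohort(synthetic.default_cohort_config(seed=11))


@pytest.fixture(scope="session")
def small_tile():
    """A quick 80/20 negative/positive tile with its ground truth."""
    cfg = synthetic.TileConfig(n_negative=80, n_positive=20, seed=1)
    return synthetic.generate_ihc_tile(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
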