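import numpy as np
import pandas as pd
import pytest

from plspair import SimConfig, generate_cohort
from plspair.io import NONRESPONDER, RESPONDER


@pytest.fixture
def default_config():
    return SimConfig(seed=7)


@pytest.fixture
def small_cohort():
    """20/20 cohort with a strong planted pair and modest background."""
    config = SimConfig(
        n_responders=20,
        n_nonresponders=20,
        n_lnc_background=50,
        n_mrna_background=50,
        n_network_nodes=40,
        seed=11,
    )
    lnc, mrna, labels, truth = generate_cohort(config)
    return config, lnc, mrna, labels, truth


@pytest.fixture
def gauss_6v6():
    """Seeded 6-vs-6 Gaussian matrix with labels, for t-test oracles."""
    rng = np.random.default_rng(42)
    samples = [f"S{i}" for i in range(12)]
    matrix = pd.DataFrame(
        rng.normal(8, 1, size=(30, 12)),
        index=[f"G{i}" for i in range(30)],
        columns=samples,
    )
    labels = pd.Series([RESPONDER] * 6 + [NONRESPONDER] * 6, index=samples)
    return matrix, labels
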