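import numpy as np
import pandas as pd
import pytest

from oxystrat import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with planted hypoxia effects, shared across tests."""
    cfg = SimulationConfig(
        n_samples=150,
        n_genes=200,
        n_signature_genes=52,
        n_taxa=50,
        n_hypoxia_taxa=5,
        hypoxia_log_hr=0.8,
        seed=20240901,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def km_hand_data():
    """Three subjects, times (1, 2, 3), events (1, 1, 0): the product-limit
    estimate is S(1)=2/3, S(2)=1/3, S(3)=1/3."""
    return pd.DataFrame(
        {
            "sample_id": ["a", "b", "c"],
            "os_time": [1.0, 2.0, 3.0],
            "os_event": [1, 1, 0],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
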