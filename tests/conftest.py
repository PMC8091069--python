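import numpy as np
import pytest

import stresscost as sc


@pytest.fixture(scope="session")
def item_map():
    return sc.default_item_map()


@pytest.fixture(scope="session")
def uniform_thresholds():
    """Thresholds from the normative sample {1, 2, ..., 100}."""
    return sc.derive_thresholds(np.arange(1, 101, dtype=float))


@pytest.fixture(scope="session")
def small_study():
    """A small seeded synthetic study with strong score separation."""
    config = sc.SimulationConfig(
        n_groups=4,
        workers_per_group=(30, 60),
        seed=11,
        score_separation=2.5,
        rate_ratio=2.0,
        n_normative=1000,
    )
    return sc.simulate_study(config)
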