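import numpy as np
import pytest

import snowsem as ss


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    cfg = ss.default_config(n_participants=240, words_per_component=20, seed=42)
    return ss.generate_study(cfg)


@pytest.fixture(scope="session")
def small_network(small_study):
    return ss.build_semantic_network(small_study.dataset, min_count=3, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
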