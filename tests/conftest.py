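import numpy as np
import pytest

import qjrmsd as q


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def degenerates():
    return q.degenerate_fixtures()


@pytest.fixture(scope="session")
def small_pairs():
    """Two dozen small random structure pairs spanning noise scales."""
    return list(q.pair_suite(24, seed=42, n_res_range=(8, 16), pairs_per_base=6))
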