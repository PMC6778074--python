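import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cluster():
    from nanodose.geometry import generate_cluster
    return generate_cluster(n=50, box_nm=1000.0, sd_max_nm=5.0, seed=7,
                            n_labeled=5)
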