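import numpy as np
import pytest

from cpgformer.simulate import MethylomeSimulator, SimConfig
from cpgformer.vocab import build_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return build_vocabulary()


@pytest.fixture(scope="session")
def small_sim():
    """Small region-level simulation shared across read-handling tests."""
    cfg = SimConfig(alpha=0.1, beta=5.0, n_regions=8, coverage=6,
                    read_length=150, seed=11)
    return MethylomeSimulator(cfg)


@pytest.fixture(scope="session")
def small_pools(small_sim):
    return small_sim.simulate()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
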