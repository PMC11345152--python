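import numpy as np
import pytest

from cpfosr import CPTensorFOSR, simulate


@pytest.fixture(scope="session")
def small_fit():
    """One fitted model on a small synthetic dataset, shared across tests."""
    y, design, truth = simulate.gen_multisubject(
        dims=(10, 10, 5), N=30, R_true=3, seed=7
    )
    res = CPTensorFOSR(y, design).fit(rank=3, M=1000, seed=7, n_restarts=1)
    return y, design, truth, res


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
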