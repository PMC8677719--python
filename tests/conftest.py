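import numpy as np
import pytest

from regscan import SimConfig
from regscan.motif import PositionMatrix
from regscan.synthetic import truth_motif


@pytest.fixture
def small_config():
    """A desk-scale simulation configuration used across tests."""
    return SimConfig(
        seed=1,
        n_bound_probes=60,
        n_background_probes=50,
        n_genes=100,
        concordant_fraction=0.2,
        noise_sd=0.1,
    )


@pytest.fixture
def kb_pfm():
    """The 10-bp palindromic kB truth motif (GGGAATTCCC, 0.85 columns)."""
    return truth_motif(10)


@pytest.fixture
def sharp_pfm():
    """A nearly deterministic 4-bp motif for exact-scan tests."""
    eps = 1e-3
    freqs = np.full((4, 4), eps / 3)
    for j, b in enumerate([0, 1, 2, 3]):  # consensus ACGT
        freqs[b, j] = 1 - eps
    return PositionMatrix(freqs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
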