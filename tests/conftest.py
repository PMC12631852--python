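import numpy as np
import pytest

from scanchor import SimConfig, generate, normalize_counts


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial generated dataset shared across tests."""
    cfg = SimConfig(n1=400, n2=400, K=4, g=100, m=12, rare_fraction=0.05,
                    seed=11)
    rna, gas, xp, truth = generate(cfg)
    return cfg, rna, gas, xp, truth


@pytest.fixture(scope="session")
def small_sim_normalized(small_sim):
    cfg, rna, gas, xp, truth = small_sim
    return cfg, normalize_counts(rna), normalize_counts(gas), xp, truth


def random_embedding_batch(rng, n=None, d=None, K=None):
    """A random batch (embedding, labels) for loss-term tests."""
    n = n or int(rng.integers(4, 33))
    d = d or int(rng.integers(2, 9))
    K = K or int(rng.integers(2, 6))
    E = rng.normal(size=(n, d))
    labels = rng.integers(0, K, size=n)
    while len(np.unique(labels)) < min(2, K):
        labels = rng.integers(0, K, size=n)
    return E, labels
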