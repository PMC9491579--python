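import numpy as np
import pytest

from methgwas import compute_kinship, simulate_genotypes
from methgwas.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_panel():
    """A small structured inbred panel reused across tests."""
    cfg = SimulationConfig(n_lines=150, n_snps=300, n_chromosomes=3, n_clusters=5, fst=0.2, seed=11)
    geno = simulate_genotypes(cfg)
    K = compute_kinship(geno)
    return cfg, geno, K


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def kinship_draw(K_values, h2, n, rng):
    """Trait with var = h2*K + (1-h2)*I, the generating model of the REML fit."""
    s, U = np.linalg.eigh((K_values + K_values.T) / 2.0)
    s = np.clip(s, 0, None)
    return U @ (np.sqrt(h2 * s) * rng.standard_normal(n)) + np.sqrt(1.0 - h2) * rng.standard_normal(n)
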