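import numpy as np
import pytest

from canopygen.simulate import (SimulationConfig, SyntheticTreeParams,
                                TraitModel, generate_tree_cloud,
                                simulate_genetics)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reference_tree():
    """One noise-free high-density tree with known truth (H=10, CBH=3,
    CW=4, CWH=6)."""
    params = SyntheticTreeParams(height=10, cbh=3, cw=4, cwh=6,
                                 n_points=10_000, noise_sd=0.0)
    cloud, truth = generate_tree_cloud(params, seed=7)
    return params, cloud, truth


@pytest.fixture(scope="session")
def halfsib_dataset():
    """Small half-sib trial: 10 families x 10 trees x 1 site, 500 SNPs."""
    cfg = SimulationConfig(n_families=10, trees_per_family=10, n_sites=1,
                           n_snps=500,
                           traits=[TraitModel(sigma2_f=0.3, sigma2_b=0.1,
                                              sigma2_e=0.6)],
                           seed=77)
    return simulate_genetics(cfg)
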