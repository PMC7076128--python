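import numpy as np
import pytest

from tadbound.simulate import SimulationSpec, simulate_matrix


@pytest.fixture
def three_domain_clean():
    """Zero-noise matrix with boundaries at bins 37, 75, 112 (n = 150)."""
    spec = SimulationSpec(n_bins=150, boundaries=(37, 75, 112), betas=0.4,
                          alpha=1.0, noise="none", sparsity=0.0)
    return simulate_matrix(spec), spec


@pytest.fixture
def noisy_pair():
    """Two independent Poisson realizations of the same three-domain spec."""
    from dataclasses import replace
    spec = SimulationSpec(n_bins=150, boundaries=(37, 75, 112), betas=0.4,
                          alpha=1.0, noise="poisson", seed=11)
    return (simulate_matrix(spec),
            simulate_matrix(replace(spec, seed=12)),
            spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
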