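import numpy as np
import pytest

from dysmap import polar_lda, synthetic
from dysmap.polar_lda import PolarLDAModel


@pytest.fixture(scope="session")
def small_cohort():
    """Small full cohort (with time series) shared by read-only tests."""
    return synthetic.simulate_cohort(seed=7, n_per_group=(8, 8, 10),
                                     n_vertices=120, n_networks=4, T=40)


@pytest.fixture(scope="session")
def mesh_atlas():
    return synthetic.make_mesh(120, 4)


def make_polar_model(seed, K=3, V=90, D=30, concentration=0.5,
                     background=1e-3):
    """A well-separated polar topic model: factor k owns the k-th V/K block."""
    rng = np.random.default_rng(seed)
    beta = np.full((K, V), background / V)
    block = V // K
    for k in range(K):
        beta[k, k * block:(k + 1) * block] += rng.dirichlet(np.ones(block))
    beta /= beta.sum(axis=1, keepdims=True)
    gamma = np.clip(rng.uniform(0.1, 0.9, (K, V)), 1e-3, 1 - 1e-3)
    theta = rng.dirichlet(np.full(K, concentration), size=D)
    return PolarLDAModel(K=K, beta=beta, gamma=gamma, theta=theta,
                         alpha=1.0, eta=0.01, kappa=1.0)


@pytest.fixture(scope="session")
def clean_polar_data():
    model = make_polar_model(123, K=3, V=300, D=120)
    data = polar_lda.generate(model, 400, seed=124)
    return model, data
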