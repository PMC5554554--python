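import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tpdanet.core_io import ExpressionDataset
from tpdanet.synthetic import analytic_covariance, dataset_from_covariance, make_spec

#: population covariance of the x -> z -> y chain with coefficients 0.8, unit noise
CHAIN_EDGES = [("x", "z", 0.8), ("z", "y", 0.8)]


@pytest.fixture(scope="session")
def chain_spec():
    return make_spec(CHAIN_EDGES, noise_sd=1.0, n_samples=500, seed=11)


@pytest.fixture(scope="session")
def chain_cov(chain_spec):
    """(names, population covariance) of the 3-node chain."""
    return analytic_covariance(chain_spec)


@pytest.fixture(scope="session")
def chain_dataset(chain_cov):
    """Dataset whose sample covariance equals the chain's population covariance."""
    names, cov = chain_cov
    return dataset_from_covariance(names, cov, n_samples=400, seed=5)


@pytest.fixture()
def small_dataset():
    """Tiny 3-variable dataset with one trait, for role/plumbing tests."""
    rng = np.random.default_rng(42)
    values = rng.normal(size=(20, 3))
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(20)],
        variable_names=["g1", "g2", "AC"],
        roles={"g1": "gene", "g2": "gene", "AC": "trait"},
        reported={"g1"},
        values=values,
    )
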