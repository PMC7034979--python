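import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from txstate.mixture import MixtureConfig, infer_expression_probabilities
from txstate.simulate import generate_catalog, generate_fixtures

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_catalog():
    """A compact synthetic catalog shared by read-only tests."""
    return generate_catalog(
        n_genes=80, n_celltypes=8, replicates=(2, 3), n_carryover_genes=3, seed=7
    )


@pytest.fixture(scope="session")
def small_fixtures(small_catalog):
    return generate_fixtures(small_catalog.truth, seed=7, n_benchmark=60)


@pytest.fixture(scope="session")
def small_inference(small_catalog):
    """Mixture inference on the small catalog at reduced sampler settings."""
    cfg = MixtureConfig(chains=2, iters=200, folds=5, seed=3)
    return infer_expression_probabilities(
        small_catalog.matrix, small_catalog.metadata, cfg
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
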