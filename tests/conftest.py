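import numpy as np
import pytest

from msnbiotyper import CohortSpec, generate_covariates
from msnbiotyper.synthetic import generate_control_hubness


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def control_cohort():
    """600 controls over two sites with hubness features from the normative family."""
    cov = generate_covariates(CohortSpec(0, 600, n_sites=2, seed=101))
    profile, truth = generate_control_hubness(cov, R=4, noise_sd=0.3, seed=102)
    return cov, profile, truth


def random_similarity(rng, R):
    W = rng.uniform(0.05, 1.0, size=(R, R))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 1.0)
    return W
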