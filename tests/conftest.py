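import numpy as np
import pytest

from actinf.free_energy import FreeEnergyContext
from actinf.geometry import softmax


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def random_context(rng, n=3, scale=1.5):
    """A random mild inference problem: unit-ish scale log messages."""
    log_prior = np.log(softmax(rng.normal(0.0, scale, n)))
    log_evidence = rng.normal(0.0, scale, n)
    return FreeEnergyContext(log_likelihood_evidence=log_evidence, log_prior=log_prior)


def random_belief(rng, n=3):
    return rng.dirichlet(np.ones(n))


@pytest.fixture
def tmaze_env():
    from actinf.tasks import build_tmaze

    return build_tmaze()
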