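"""Shared fixtures: the default synthetic scene and the independent-neuron
cohort are expensive to generate, so they are session-scoped and shared
between module tests and the acceptance suite."""

import numpy as np
import pytest

from spikespectra.core import SpikeTrain
from spikespectra.synthetic import generate_independent_neurons, generate_population

SEED = 0


def poisson_train(mu: float, duration: float, seed: int) -> SpikeTrain:
    """Homogeneous Poisson spike train (uniform order statistics)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(mu * duration)
    return SpikeTrain(np.sort(rng.random(n) * duration), duration)


@pytest.fixture(scope="session")
def default_scene():
    """The default desk-scale population: 40 coupled neurons, 2 h, 30%
    antiphase with the shared arousal latent, pupil surrogate attached."""
    return generate_population(n_neurons=40, duration=7200.0,
                               antiphase_fraction=0.3, seed=SEED)


@pytest.fixture(scope="session")
def cohort():
    """20 independent beta=0.4 doubly-stochastic neurons, 2 h each."""
    return generate_independent_neurons(n_neurons=20, duration=7200.0,
                                        beta=0.4, seed=SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
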