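import numpy as np
import pytest

import fimdesign as fd
from fimdesign.datagen import NoiseModel, sample_true_parameters, startup_data
from fimdesign.fitting import PenaltyConfig


@pytest.fixture(scope="session")
def model():
    return fd.build_model1()


@pytest.fixture(scope="session")
def truth(model):
    return sample_true_parameters(model, 7)


@pytest.fixture(scope="session")
def noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def penalty(model):
    return PenaltyConfig.default_for(model)


@pytest.fixture(scope="session")
def startup(model, truth, noise):
    """Wild-type microarray dataset at the session truth."""
    return startup_data(model, truth, noise, 11)


@pytest.fixture(scope="session")
def random_params(model):
    """A handful of random parameter sets from the truth sampler."""
    return [sample_true_parameters(model, s) for s in range(100, 110)]


@pytest.fixture(scope="session")
def startup_fit(model, startup, penalty):
    """One converged local minimum of the startup data (warm-started from
    a random draw so the optimization is cheap but non-trivial)."""
    from fimdesign.fitting import best_fit, multistart

    results = multistart(startup, model, penalty, 6, 21)
    best = best_fit(results)
    assert best is not None and best.converged
    return best
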