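import numpy as np
import pytest

from semvis.feature_space import fit_feature_space
from semvis.simulation import (
    make_standard_feature_model,
    make_standard_world,
    make_toy_extractor,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_extractor():
    return make_toy_extractor(channels=16, image_size=32, seed=0)


@pytest.fixture(scope="session")
def toy_feature_model(toy_extractor):
    """Feature-space model fitted on the toy extractor's activation corpus."""
    gen = np.random.default_rng(7)
    corpus = np.stack(
        [toy_extractor.features(gen.random((32, 32, 3))) for _ in range(60)]
    )
    return fit_feature_space(corpus)


@pytest.fixture(scope="session")
def small_world():
    """Compact synthetic world for fast recovery tests."""
    return make_standard_world(m=16, d=12, v=24, n_clusters=4, noise_sd=0.3, seed=5)


@pytest.fixture(scope="session")
def small_feature_model(small_world):
    return make_standard_feature_model(v=small_world.n_visual, n_corpus=200, seed=5)


@pytest.fixture(scope="session")
def small_trials(small_world, small_feature_model):
    return simulate_experiment(small_world, small_feature_model, t=600, seed=11)
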