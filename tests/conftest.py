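import numpy as np
import pytest

import tcgrad as t


@pytest.fixture(scope="session")
def small_cfg():
    return t.SynthConfig(n_seeds=120, n_parcels=30, rng_seed=7)


@pytest.fixture(scope="session")
def small_geom(small_cfg):
    return t.make_geometry(small_cfg)


@pytest.fixture(scope="session")
def study_cfg():
    """The default study conditions: 600 seeds, 100 parcels."""
    return t.SynthConfig(rng_seed=0)


@pytest.fixture(scope="session")
def study_geom(study_cfg):
    return t.make_geometry(study_cfg)


@pytest.fixture(scope="session")
def study_counts(study_geom, study_cfg):
    return t.simulate_sc_counts(study_geom, study_cfg)


@pytest.fixture(scope="session")
def study_norm(study_counts):
    return t.normalize_columns_max(study_counts)


@pytest.fixture(scope="session")
def study_gradients(study_counts):
    return t.structural_gradients(study_counts)


@pytest.fixture(scope="session")
def study_distances(study_geom):
    return t.pairwise_distances(study_geom.seeds)


@pytest.fixture(scope="session")
def study_surrogate_generator(study_distances):
    return t.SurrogateGenerator(study_distances)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
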