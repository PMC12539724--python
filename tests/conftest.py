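import numpy as np
import pytest

from covermap.synthetic_scene import NDVIParams, SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config():
    return SceneConfig(n_rows=60, n_cols=60, years=(2013, 2014, 2015),
                       n_counties=3, cc_adoption_rate=0.3,
                       contamination_rate=0.1, n_truth_points=120, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    """Perfect NDVI separation: zero spread in both distributions."""
    return SceneConfig(n_rows=50, n_cols=50, years=(2013,),
                       n_counties=2, cc_adoption_rate=0.4,
                       contamination_rate=0.2, n_truth_points=100,
                       ndvi_params=NDVIParams(cover_sd=0.0, bare_sd=0.0),
                       seed=11)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    return generate_scene(noiseless_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
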