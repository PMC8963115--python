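import numpy as np
import pytest
from hypothesis import settings

from cyresick.scenes import packaged_scene_table
from cyresick.synthetic import EffectConfig, gen_panel, gen_scores

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scene_table():
    return packaged_scene_table()


@pytest.fixture(scope="session")
def small_panel():
    return gen_panel(24, seed=11)


@pytest.fixture(scope="session")
def full_panel():
    return gen_panel(154, seed=5)


@pytest.fixture(scope="session")
def study_scores(full_panel, scene_table):
    """A full-size synthetic rating matrix under default study conditions."""
    scores, latent = gen_scores(full_panel, scene_table, EffectConfig(), seed=7)
    return scores, latent


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
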