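import numpy as np
import pytest

from carotidshift import (PhantomConfig, analyze_pair, displace_scene,
                          generate_scene, sample_bone_motions)


@pytest.fixture(scope="session")
def coarse_config():
    return PhantomConfig.coarse(seed=3)


@pytest.fixture(scope="session")
def pre_scene(coarse_config):
    """Half-resolution pre-pose scene shared across the suite."""
    return generate_scene(coarse_config)


@pytest.fixture(scope="session")
def motions(pre_scene):
    return sample_bone_motions(pre_scene, 5, skull_motion=True)


@pytest.fixture(scope="session")
def post_scene(pre_scene, motions):
    return displace_scene(pre_scene, motions)


@pytest.fixture(scope="session")
def analysis(pre_scene, post_scene):
    """Full pipeline result on the shared coarse pair."""
    return analyze_pair(pre_scene, post_scene)


@pytest.fixture(scope="session")
def default_scene():
    """Full-resolution (0.43 x 0.43 x 0.5 mm) pre-pose scene."""
    return generate_scene(PhantomConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
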