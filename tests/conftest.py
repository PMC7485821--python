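import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
hyp_settings.load_profile("suite")

from pipeopt.space import ParameterSpec, SearchSpace
from pipeopt.synth import SceneSpec, generate_sample


@pytest.fixture(scope="session")
def scene_sample():
    """One default synthetic scene, shared across tests (read-only)."""
    return generate_sample(SceneSpec(seed=0))


@pytest.fixture(scope="session")
def single_cell_sample():
    """A scene with one cell, for the secondary-stage checks."""
    return generate_sample(SceneSpec(seed=0, n_cells=1))


@pytest.fixture
def two_spec_space():
    return SearchSpace(
        [
            ParameterSpec("alpha", "float", 0.0, 1.0, 0.25),
            ParameterSpec("beta", "integer", 1, 5, 2),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
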