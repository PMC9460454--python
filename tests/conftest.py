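import numpy as np
import pytest

from semd import SceneSpec, generate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """A small synthetic dataset (4 strata × 3 scenes at 48², seeded)."""
    from semd import generate_dataset

    root = tmp_path_factory.mktemp("ds")
    generate_dataset(3, 48, 7, root)
    return root


@pytest.fixture(scope="session")
def sample_scene():
    return generate_scene(SceneSpec(n_trees=1, background="simple", canvas=96, seed=5))
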