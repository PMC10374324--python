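import numpy as np
import pytest

from grapedet.architecture import ArchitectureSpec, build_model
from grapedet.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def tiny_spec() -> ArchitectureSpec:
    """CPU-scale detector configuration used across tests."""
    return ArchitectureSpec(input_size=128, num_classes=1,
                            stage_repeats=(1, 1, 1, 1, 1), width_mult=0.25)


@pytest.fixture(scope="session")
def tiny_model(tiny_spec):
    return build_model(tiny_spec, seed=0).eval()


@pytest.fixture(scope="session")
def two_scenes():
    """Two single-bunch synthetic orchard images with annotations."""
    samples = []
    for i in range(2):
        image, ann, info = generate_scene(
            SceneSpec(image_size=128, n_bunches=1, seed=100 + i, background_clutter=0.3))
        samples.append((image, ann))
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
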