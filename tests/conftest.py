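import numpy as np
import pytest

from cytoseg import PhantomSpec, generate_scene


@pytest.fixture(scope="session")
def herlev_scene():
    """One tight-crop single-cell phantom with its ground truth."""
    return generate_scene(PhantomSpec.herlev(seed=100))


@pytest.fixture(scope="session")
def multicell_scene():
    """One 384×384 three-cell scene with moderate overlap."""
    spec = PhantomSpec(n_cells=3, overlap_fraction=0.2, seed=0).with_size((384, 384))
    return generate_scene(spec)


@pytest.fixture(scope="session")
def disjoint_scene():
    """One 384×384 three-cell scene with disjoint cells."""
    spec = PhantomSpec(n_cells=3, overlap_fraction=0.0, seed=3).with_size((384, 384))
    return generate_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
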