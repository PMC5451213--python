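import numpy as np
import pytest

from histocomp.genome import GenomeModel
from histocomp.synthetic import SyntheticStackSpec, generate_embryo_stack


@pytest.fixture(scope="session")
def genome():
    return GenomeModel()


@pytest.fixture(scope="session")
def small_spec():
    """A small, quick stack spec used by several imaging tests."""
    return SyntheticStackSpec(
        grid_shape=(48, 96, 96),
        voxel_size=(1.0, 0.5, 0.5),
        cap_radius=20.0,
        n_nuclei=8,
        nucleus_radius=(3.5, 0.0),
        nc_ratio=5.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noisefree_stack(small_spec):
    return generate_embryo_stack(small_spec)


@pytest.fixture(scope="session")
def noisy_stack(small_spec):
    spec = SyntheticStackSpec(
        **{**small_spec.__dict__, "noise_sigma": 20.0, "seed": 11}
    )
    return spec, *generate_embryo_stack(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
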