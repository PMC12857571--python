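import numpy as np
import pytest

from surffold.model import ModelConfig, featurize_structure
from surffold.structure import SyntheticSpec, make_synthetic_structure
from surffold.surface import SurfaceConfig


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def helix30():
    return make_synthetic_structure(SyntheticSpec(n_residues=30, seed=7))


@pytest.fixture(scope="session")
def helix50():
    return make_synthetic_structure(SyntheticSpec(n_residues=50, seed=11))


@pytest.fixture(scope="session")
def small_config():
    """Coarse surface + narrow widths: fast enough for per-test reuse."""
    return ModelConfig(
        d_struct=32, d_surf=32, d_fuse=32, n_heads=4,
        surface=SurfaceConfig(target_spacing=3.0, seed=0),
    )


@pytest.fixture(scope="session")
def featurized30(helix30, small_config):
    return featurize_structure(helix30, small_config)


@pytest.fixture(scope="session")
def overfit_dataset():
    """Five 30-residue synthetic proteins under the default configuration."""
    config = ModelConfig(surface=SurfaceConfig(target_spacing=3.0, seed=0))
    structures = [
        make_synthetic_structure(SyntheticSpec(n_residues=30, seed=100 + i))
        for i in range(5)
    ]
    return config, [featurize_structure(s, config) for s in structures]
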