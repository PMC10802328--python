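import numpy as np
import pytest

from catrace.config import ModelConfig
from catrace.voxnet import build_voxel_classifier


@pytest.fixture(scope="session")
def atom_classifier():
    """Full-size atom-type classifier (4 output channels)."""
    return build_voxel_classifier(ModelConfig(out_channels=4), seed=11)


@pytest.fixture(scope="session")
def aa_classifier():
    """Full-size amino-acid-type classifier (21 output channels)."""
    return build_voxel_classifier(ModelConfig(out_channels=21), seed=12)


@pytest.fixture(scope="session")
def small_config():
    """Thin transformer, full-size decoder: fast forward-pass contracts."""
    return ModelConfig(embed_dim=96, n_heads=4, mlp_dim=192, n_blocks=4,
                       skip_blocks=(1, 2, 3, 4), out_channels=4)


@pytest.fixture(scope="session")
def small_classifier(small_config):
    return build_voxel_classifier(small_config, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
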