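import numpy as np
import pytest

import fragclr as fc
from fragclr.encoders import EncoderConfig, TwoBranchModel


@pytest.fixture(scope="session")
def toy_graphs():
    return [fc.parse_smiles(s) for s in fc.toy_corpus()]


@pytest.fixture(scope="session")
def random_corpus_graphs():
    smiles = fc.random_molecules(
        fc.FixtureSpec(n_molecules=60, seed=5, max_heavy_atoms=10,
                       ring_probability=0.2)
    )
    return [fc.parse_smiles(s) for s in smiles]


@pytest.fixture(scope="session")
def small_cfg():
    return EncoderConfig(embedding_dim=16, message_passing_steps=2,
                         readout_steps=2, fusion_layers=1, fusion_heads=4,
                         projection_hidden_dim=16, seed=0)


@pytest.fixture(scope="session")
def small_model(small_cfg):
    return TwoBranchModel(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
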