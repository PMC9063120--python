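import numpy as np
import pytest

from ginplans import chem, gin, synthetic


@pytest.fixture(scope="session")
def small_molecules():
    """Sixty valid synthetic SMILES shared across tests."""
    return synthetic.generate_molecules(60, seed=5)


@pytest.fixture(scope="session")
def small_graphs(small_molecules):
    graphs, dropped = chem.graphs_from_smiles(small_molecules)
    assert not dropped
    return graphs


@pytest.fixture(scope="session")
def tiny_gin():
    """Small random-initialised GIN for forward-pass contracts."""
    config = gin.GINConfig(n_layers=3, node_mlp_hidden=(32, 16), embed_dim=16,
                           head_hidden=(32,), out_dim=128, seed=0)
    params = gin.init_params(config, seed=0)
    return params, config


@pytest.fixture(scope="session")
def pretrain_data(small_molecules, small_graphs):
    fps = [chem.compute_ecfp(chem.parse_smiles(s), radius=2, n_bits=128)
           for s in small_molecules]
    return list(zip(small_graphs, [np.asarray(f) for f in fps]))
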