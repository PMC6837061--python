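import numpy as np
import pytest

from molbayes.molgraph import parse_smiles
from molbayes.mpnn import MPNNConfig, MPNNModel
from molbayes.synthetic import generate_molecule_library, label_library


@pytest.fixture(scope="session")
def tiny_config() -> MPNNConfig:
    """Small architecture: fast enough for finite differences and loops."""
    return MPNNConfig(steps=2, hidden=4, fingerprint=6, head_hidden=(5, 4))


@pytest.fixture(scope="session")
def tiny_model(tiny_config) -> MPNNModel:
    return MPNNModel(tiny_config)


@pytest.fixture(scope="session")
def small_library():
    """20 parsed molecules with noisy labels and ground truth."""
    smiles, families = generate_molecule_library(20, seed=7)
    table = label_library(smiles, seed=8)
    table["family"] = families
    graphs = [parse_smiles(s) for s in smiles]
    return graphs, table


@pytest.fixture(scope="session")
def three_molecule_batch():
    graphs = [parse_smiles(s) for s in ("CCO", "c1ccccc1", "CC(=O)N")]
    y = np.array([1.0, -0.5, 2.0])
    return graphs, y
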