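import numpy as np
import pytest

from domseg import ProteinChain
from domseg.network import NetworkConfig, TrainingConfig, build_model, train
from domseg.synthetic import make_dataset


def make_chain(coords, start_number=1, chain_id="A"):
    coords = np.asarray(coords, dtype=float)
    residues = tuple((start_number + i, "A") for i in range(coords.shape[0]))
    return ProteinChain(chain_id, residues, coords)


@pytest.fixture
def straight_chain():
    """10 residues on a line at consecutive-Cα spacing."""
    return make_chain(np.c_[3.8 * np.arange(10), np.zeros(10), np.zeros(10)])


@pytest.fixture
def ideal_helix_chain():
    """12-residue ideal alpha helix (rise 1.5 Å, radius 2.3 Å, 100°/residue)."""
    t = np.arange(12) * np.deg2rad(100.0)
    coords = np.c_[2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(12)]
    return make_chain(coords)


# Mini-training conditions shared by the parameter-recovery test and the
# end-to-end CLI test: 8-block/16-filter model, 200 synthetic chains,
# 10 epochs, fixed seeds.
MINI_TRAIN_DATASET_SEED = 11
MINI_TRAIN_MODEL_SEED = 0
MINI_TRAIN_CONFIG = NetworkConfig(n_blocks=8, n_filters=16)


@pytest.fixture(scope="session")
def mini_trained_model():
    dataset = make_dataset(200, seed=MINI_TRAIN_DATASET_SEED)
    model = build_model(MINI_TRAIN_CONFIG, seed=MINI_TRAIN_MODEL_SEED)
    result = train(model, dataset, TrainingConfig(epochs=10, seed=0))
    return model, result
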