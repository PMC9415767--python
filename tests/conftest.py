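import numpy as np
import pytest

from afens.surgery import tiny_net_graph
from afens.synthetic import ToySpec, generate_toy_arrays
from afens.training import ImageDataset, SplitDataset, TrainConfig


@pytest.fixture(scope="session")
def toy_split():
    """Four-class blob dataset at sigma=0.5, split 140 train / 60 test."""
    spec = ToySpec(n_classes=4, samples_per_class=50, image_size=32,
                   signal="blob", sigma=0.5, seed=3)
    X, y = generate_toy_arrays(spec)
    idx = np.random.default_rng(0).permutation(len(X))
    tr, te = idx[:140], idx[140:]
    return SplitDataset(ImageDataset(X[tr], y[tr]),
                        ImageDataset(X[te], y[te]))


@pytest.fixture(scope="session")
def graph():
    return tiny_net_graph(n_classes=4)


@pytest.fixture()
def fast_config():
    """Desk-scale training config: from-scratch TinyNet, a few epochs."""
    return TrainConfig(batch_size=30, base_lr=0.01,
                       final_layer_lr_multiplier=2.0, epochs=6, seed=1)
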