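import numpy as np
import pytest

import ffcnn as F


@pytest.fixture(scope="session")
def shapes4():
    """4-class synthetic shape splits at desk scale (fast)."""
    train = F.generate_synthetic(
        F.SyntheticConfig(n_classes=4, images_per_class=50, image_side=16,
                          noise_sd=0.05, seed=7)
    )
    test = F.generate_synthetic(
        F.SyntheticConfig(n_classes=4, images_per_class=25, image_side=16,
                          noise_sd=0.05, seed=7),
        split="test",
    )
    return train, test


@pytest.fixture(scope="session")
def fourier4():
    return F.default_fourier_bank(4)


@pytest.fixture(scope="session")
def tiny_net(shapes4, fourier4):
    """A briefly trained 3x4-filter network shared by inference tests."""
    train, _ = shapes4
    net = F.FFNetwork((1, 16, 16), n_layers=3, filters=4, kernel=7,
                      n_classes=4, seed=1)
    tc = F.TrainConfig(epochs=8, lr=3e-3, batch_size=16, K=0.35, seed=1,
                       track_accuracy=False)
    net, history = F.train_ff(net, train, fourier4, tc)
    return net, history


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
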