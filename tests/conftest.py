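import numpy as np
import pytest

from stedit.gan import GanConfig, train_gan
from stedit.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale study conditions shared by most tests (300 cells/class)."""
    return SimConfig.default(n0=300, n1=300, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def trained_gan(small_dataset):
    """One smoke-trained GAN shared by the generation/inversion tests."""
    cfg = GanConfig(p=small_dataset.cfg.p, iters=800, ckpt_every=200, seed=5)
    return train_gan(small_dataset, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
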