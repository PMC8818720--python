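import numpy as np
import pytest

from wallshear.geometry import build_coarse_template
from wallshear.synthetic import FlowModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trained():
    """Reduced-scale training run shared by the end-to-end tests.

    Eight tapered-tube geometries (6 train / 1 val / 1 test), (8, 16, 32)
    filters, fixed (1.0, 2.0) mm sheet pair, 10 epochs over a 1024-patch pool.
    """
    from wallshear.nn import TrainConfig, train
    from wallshear.nn.train import AugmentConfig
    from wallshear.nn.unet import reduced_config
    from wallshear.synthetic import make_dataset

    data = make_dataset(n_geometries=8, seed=7)
    cfg = TrainConfig(
        epochs=10, patch_pool=1024, seed=3, lr_max=1e-3, lr_cycle=5,
        sheet_pairs=[(1.0, 2.0)],
        augment=AugmentConfig(rotate=False),
    )
    model, history = train(data["train"], data["val"], reduced_config(3), cfg)
    return data, cfg, model, history


@pytest.fixture
def small_tube():
    """24 x 31 cylinder, radius 10 mm, length 60 mm, axis z."""
    z = np.linspace(0.0, 60.0, 31)
    cl = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)
    return build_coarse_template(24, 31, cl, 10.0)


@pytest.fixture
def steady_model():
    """Steady Poiseuille tube: R = 10 mm, Vmax = 1 m/s, mu = 4e-3 Pa s."""
    return FlowModel(R=10.0, Vmax_peak=1.0, baseline=1.0, taper_amplitude=0.0)
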