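import numpy as np
import pytest

from recruitkin import synth


@pytest.fixture(scope="session")
def noiseless_movie():
    """Small deterministic drift-free movie with no noise or bleaching."""
    cfg = synth.StripeSimConfig(
        n_cells=2,
        image_shape=(120, 200),
        shot_noise=False,
        read_sigma=0.0,
        seed=7,
    )
    stack, rois, truth = synth.simulate_stripe_movie(cfg)
    return cfg, stack, rois, truth


@pytest.fixture(scope="session")
def noisy_movie():
    """Default-noise movie used by statistics tests."""
    cfg = synth.StripeSimConfig(n_cells=4, image_shape=(120, 200), seed=11)
    stack, rois, truth = synth.simulate_stripe_movie(cfg)
    return cfg, stack, rois, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
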