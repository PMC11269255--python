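import numpy as np
import pytest

from noisemapnet.phantom import PhantomSpec


@pytest.fixture
def perfusion_spec():
    return PhantomSpec(image_size=(64, 64), lv_radius=10.0,
                       myocardium_outer_radius=18.0, n_dynamics=30, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
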