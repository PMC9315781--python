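import numpy as np
import pytest

import fishweigh as fw
from fishweigh.synthetic import CameraModel, GrowthModel


@pytest.fixture(scope="session")
def default_table():
    """A full-size synthetic observation table under default noise."""
    return fw.make_file_dataset(2777, seed=7)


@pytest.fixture(scope="session")
def trained_cascade(default_table):
    with pytest.warns(UserWarning):  # exactly proportional width/length columns
        return fw.train_cascade(default_table, seed=0)


@pytest.fixture(scope="session")
def noiseless_setup():
    """Generator with every noise source off: pixel noise, depth quantisation,
    and individual weight variation."""
    growth = GrowthModel(anchor_sd_weights_g=(0.0, 0.0))
    camera = CameraModel(marker_spacing_cm=None)
    table = fw.make_file_dataset(600, camera=camera, growth=growth, seed=3,
                                 pixel_noise_sd=0.0)
    return growth, camera, table


@pytest.fixture(scope="session")
def noiseless_cascade(noiseless_setup):
    _, _, table = noiseless_setup
    with pytest.warns(UserWarning):
        return fw.train_cascade(table, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
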