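import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from mptexture import fov_io, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def class_params():
    """Class-mean liver/tumor tissue parameters at full separation."""
    return synthetic.CohortSpec(n_patients=1).class_means()


@pytest.fixture
def small_fov(class_params):
    """One quick quarter-size FoV of liver tissue."""
    liver, _ = class_params
    return synthetic.render_fov(liver, shape=(76, 151), rng=7)


def make_channel(pixels, name="TPEF", normalize=True):
    """Helper: wrap an array as a (optionally normalized) ChannelImage."""
    img = fov_io.ChannelImage(pixels=np.asarray(pixels), channel_name=name)
    return fov_io.minmax_normalize(img) if normalize else img
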