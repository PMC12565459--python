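import numpy as np
import pytest

from edemagrade.phantom import PhantomParams, generate_subject
from edemagrade.radiomics.roi import DiscretizedROI


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    return PhantomParams(volume_shape=(32, 32, 32), n_subjects=10, seed=7)


@pytest.fixture(scope="session")
def hgg_subject(small_params):
    return generate_subject(small_params, "HGG", np.random.default_rng(7), "sub-hgg")


@pytest.fixture(scope="session")
def lgg_subject(small_params):
    return generate_subject(small_params, "LGG", np.random.default_rng(8), "sub-lgg")


@pytest.fixture()
def tiny_levels() -> DiscretizedROI:
    """Random 6x6x3 discretized ROI with 4 gray levels and a few holes."""
    rng = np.random.default_rng(42)
    lev = rng.integers(1, 5, size=(6, 6, 3))
    holes = rng.random(lev.shape) < 0.15
    lev[holes] = 0
    return DiscretizedROI(levels=lev.astype(np.int64), Ng=4, bin_width=25.0)
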