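import numpy as np
import pytest

from fnirsnet.montage import default_montage
from fnirsnet.paradigm import make_paradigm
from fnirsnet.preprocess import HemoSeries


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def paradigm():
    return make_paradigm()


def make_hemo(hbo: np.ndarray, paradigm) -> HemoSeries:
    """Wrap a channels x time array as a HemoSeries with paradigm annotations."""
    hbo = np.asarray(hbo, dtype=float)
    return HemoSeries(hbo=hbo, hbr=-hbo / 3.0, sampling_rate=paradigm.sampling_rate,
                      paradigm=paradigm)


@pytest.fixture(scope="session")
def roi_sets(montage):
    return {
        "sm1_left": montage.roi("SM1", "left").channels,
        "sm1_right": montage.roi("SM1", "right").channels,
    }
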