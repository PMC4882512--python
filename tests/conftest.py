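import numpy as np
import pytest

from saltatrack.synthetic_data import ImagingParams


@pytest.fixture
def imaging_short():
    """A 1-minute, single-plane imaging run for fast unit tests."""
    return ImagingParams(duration=60.0, n_z=1)


@pytest.fixture
def imaging_default():
    return ImagingParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
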