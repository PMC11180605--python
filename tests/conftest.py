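import numpy as np
import pytest

from riscbleach.calibration import calibrate_anchors, egfp_anchors
from riscbleach.photophysics import Illumination, egfp_default_params

REF_ILLUM = Illumination(470.0, 32.0, 900.0, 2000.0)


@pytest.fixture(scope="session")
def egfp_params():
    """The shipped calibrated EGFP-like parameter set."""
    return egfp_default_params()


@pytest.fixture(scope="session")
def ref_illum():
    return REF_ILLUM


@pytest.fixture(scope="session")
def calibrated_fit():
    """A fresh anchor calibration (seed 0), shared across tests."""
    return calibrate_anchors(egfp_anchors(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
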