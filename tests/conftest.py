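import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ncsf import (CrfParams, CsfParams, FitGrid, HrfSpec, NcsfParams,
                  build_design, standard_csf_params)


@pytest.fixture(scope="session")
def design():
    """Default 214-volume stimulus protocol."""
    return build_design()


@pytest.fixture(scope="session")
def hrf():
    return HrfSpec()


@pytest.fixture(scope="session")
def standard_csf():
    return standard_csf_params()


@pytest.fixture(scope="session")
def green_truth():
    return NcsfParams(csf=CsfParams(cs_p=150.0, sf_p=1.0, width_r=1.3),
                      crf=CrfParams(slope_crf=3.0, amplitude=1.0),
                      baseline=0.0)


@pytest.fixture(scope="session")
def red_truth():
    return NcsfParams(csf=CsfParams(cs_p=100.0, sf_p=2.0, width_r=1.0),
                      crf=CrfParams(slope_crf=3.0, amplitude=1.0),
                      baseline=0.0)


@pytest.fixture(scope="session")
def small_grid():
    """3x3x3x3 grid for exhaustive-scan comparisons."""
    return FitGrid(sf_p=np.array([0.5, 2.0, 8.0]),
                   cs_p=np.array([20.0, 100.0, 300.0]),
                   width_r=np.array([0.5, 1.0, 2.0]),
                   slope_crf=np.array([1.0, 3.0, 6.0]))
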