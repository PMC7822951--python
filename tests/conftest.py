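"""Shared fixtures: the reference optical configuration and its calibration.

The axial response of the reference configuration (642-nm excitation at
69.5 deg, NA 1.42, 670-nm emission, alpha = 0.9, N0 = 51,000) is used
by most modules and is expensive enough to build once per session.
"""

import numpy as np
import pytest

from simpler_tirf import (
    AcquisitionParams,
    CalibrationBundle,
    OpticalConfig,
    axial_response,
)


@pytest.fixture(scope="session")
def paper_config() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def paper_response(paper_config):
    return axial_response(paper_config)


@pytest.fixture(scope="session")
def paper_bundle(paper_response) -> CalibrationBundle:
    return CalibrationBundle.from_response(paper_response)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def acq_params() -> AcquisitionParams:
    # DNA-PAINT-like: over-dispersed counts (c = 5), ~5-nm lateral noise
    return AcquisitionParams(
        n_frames=20000, mean_on_frames=6.0, sigma_n_factor=5.0, sigma_xy_nm=5.0
    )
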