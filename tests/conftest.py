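"""Shared fixtures: default optics, astigmatic coefficients, cached engines."""

import pytest

from dipoleloc import (
    DipolePSFEngine,
    OpticalConfig,
    ZernikeCoefficients,
)

W6_NM = 0.11 * 680.0  # the study's vertical astigmatism, ~75 nm RMS


@pytest.fixture(scope="session")
def cfg() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def astig() -> ZernikeCoefficients:
    return ZernikeCoefficients({6: W6_NM})


@pytest.fixture(scope="session")
def no_astig() -> ZernikeCoefficients:
    return ZernikeCoefficients({})


@pytest.fixture(scope="session")
def sim_engine(cfg, astig) -> DipolePSFEngine:
    """Simulation-grade engine: 17 px ROI, 9x oversampling, 128 pupil samples."""
    return DipolePSFEngine(cfg, astig, roi_px=17, oversampling=9)


@pytest.fixture(scope="session")
def sim_engine_noastig(cfg, no_astig) -> DipolePSFEngine:
    return DipolePSFEngine(cfg, no_astig, roi_px=17, oversampling=9)
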