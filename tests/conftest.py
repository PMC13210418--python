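"""Shared fixtures: physics inputs and trained models built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import pcdspect as p
from pcdspect.decomp import MLPHyper, fit_mlp


@pytest.fixture(scope="session")
def spectrum():
    return p.load_spectrum()


@pytest.fixture(scope="session")
def mu_al():
    return p.load_attenuation("Al")


@pytest.fixture(scope="session")
def mu_pmma():
    return p.load_attenuation("PMMA")


@pytest.fixture(scope="session")
def mu_cdte():
    return p.load_attenuation("CdTe")


@pytest.fixture(scope="session")
def det_config():
    return p.DetectorConfig()


@pytest.fixture(scope="session")
def drf(det_config):
    return p.build_drf(det_config)


@pytest.fixture(scope="session")
def thresholds_m4():
    return p.ThresholdConfig.equally_spaced(4)


@pytest.fixture(scope="session")
def grid8_m4(spectrum, drf, thresholds_m4):
    return p.make_calibration_grid(8, spectrum, drf, thresholds_m4)


@pytest.fixture(scope="session")
def poly_model(grid8_m4):
    return p.fit_poly2(grid8_m4)


@pytest.fixture(scope="session")
def svr_model(grid8_m4):
    return p.fit_svr(grid8_m4)


@pytest.fixture(scope="session")
def mlp_model(grid8_m4):
    return fit_mlp(grid8_m4, MLPHyper(seed=0))


@pytest.fixture(scope="session")
def quant_phantom():
    return p.build_quant_phantom()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
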