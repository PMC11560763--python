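import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import il6loop as il

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    return il.load_config()


@pytest.fixture(scope="session")
def melanoma_system(config):
    return il.monoculture("melanoma", config)


@pytest.fixture(scope="session")
def cd4_system(config):
    return il.monoculture("cd4", config)


@pytest.fixture(scope="session")
def coculture_system(config):
    return il.coculture(config)


@pytest.fixture(scope="session")
def panel_result(config):
    """The 10-condition panel under shipped defaults (computed once)."""
    return il.run_panel(il.standard_panel(), config)


@pytest.fixture(scope="session")
def melanoma_scan(melanoma_system):
    """The published E2F1 scan protocol: 0.1-100 a.u., readout at 100 h."""
    return il.scan_E2F1(melanoma_system, lo=0.1, hi=100.0, n=41)


@pytest.fixture(scope="session")
def cd4_scan(cd4_system):
    return il.scan_E2F1(cd4_system, lo=0.1, hi=100.0, n=41)


@pytest.fixture(scope="session")
def scan2d(melanoma_system):
    """The published 2-D protocol: E2F1 x STAT3, 0.1-10 a.u., 100 h readout."""
    return il.scan_E2F1_STAT3(melanoma_system, lo=0.1, hi=10.0, n=25)


@pytest.fixture(scope="session")
def pwms():
    return il.load_builtin_pwms()


def hill_scan(h: float, K: float = 1.0, lo: float = 1e-2, hi: float = 1e2,
              n: int = 41, ymax: float = 10.0):
    """Exact Hill dose-response packaged as a ScanResult (closed-form oracle)."""
    from il6loop.analysis import ScanResult

    grid = np.geomspace(lo, hi, n)
    response = ymax * grid ** h / (K ** h + grid ** h)
    return ScanResult(knob="E2F1", grid=grid, response=response,
                      protocol={"closed_form": True})
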