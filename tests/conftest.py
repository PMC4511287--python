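import numpy as np
import pytest

from taskneg.protocol import HrfParams, build_design_matrix, rs_spec
from taskneg.synth import NoiseParams, make_ground_truth


@pytest.fixture(scope="session")
def rs_timeline():
    """The repetitive-speech run protocol (165 volumes at TR 3 s)."""
    return rs_spec(seed=0)


@pytest.fixture(scope="session")
def small_truth():
    """Desk-scale antagonistic ground truth: 20^3 grid, 10% responders per
    sign at +/-1% signal change."""
    return make_ground_truth("antagonistic", seed=1)


@pytest.fixture(scope="session")
def gating_truth():
    return make_ground_truth("gating", seed=1)


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise-free generator settings (only the deterministic signal)."""
    return NoiseParams(white_sd=0.0, drift_amplitude=0.0, motion_amplitude=0.0, seed=7)


@pytest.fixture(scope="session")
def default_noise():
    """The study conditions: SNR 1 (1% amplitude vs 1% noise sd), AR(1) 0.3,
    1-cycle drift, mild motion coupling."""
    return NoiseParams(seed=7)
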