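import numpy as np
import pytest

from capox.decay import CalibrationCurve
from capox.oximetry import HillParams
from capox.simulate import GroundTruthProfile, SimulationConfig


@pytest.fixture(scope="session")
def calib() -> CalibrationCurve:
    """Default Stern-Volmer curve: tau0 = 40 us, kq = 250 /s/mmHg."""
    return CalibrationCurve()


@pytest.fixture(scope="session")
def hill() -> HillParams:
    return HillParams()


@pytest.fixture(scope="session")
def profile() -> GroundTruthProfile:
    return GroundTruthProfile()


@pytest.fixture()
def short_config() -> SimulationConfig:
    """0.6-s acquisition (2000 cycles), the study's standard protocol."""
    return SimulationConfig(n_cycles=2000)


@pytest.fixture()
def long_config() -> SimulationConfig:
    """9-s acquisition (30000 cycles) used for EAT and fluctuations."""
    return SimulationConfig(n_cycles=30000)


def noiseless_histogram(amplitude, tau_us, offset, n_bins=290, bin_width=1.0):
    """Exact expected counts of a single-exponential decay histogram."""
    from capox.decay import DecayHistogram

    edges = np.arange(n_bins + 1) * bin_width
    t = 0.5 * (edges[:-1] + edges[1:])
    return DecayHistogram(edges, amplitude * np.exp(-t / tau_us) + offset)
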