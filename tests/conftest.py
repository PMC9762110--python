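import numpy as np
import pytest

from dceprost.aif import AifSpec, parker_aif, weinmann_aif
from dceprost.conversion import acquisition_preset


@pytest.fixture(scope="session")
def acq36():
    """120 x 3.6 s acquisition preset."""
    return acquisition_preset("120x3.6")


@pytest.fixture(scope="session")
def acq72():
    """60 x 7.2 s acquisition preset."""
    return acquisition_preset("60x7.2")


@pytest.fixture(scope="session")
def times36(acq36):
    return acq36.times


@pytest.fixture(scope="session")
def fine_times(times36):
    """Half-second grid covering the 3.6 s protocol, for AIF evaluation."""
    return np.arange(0.0, times36.max() + 1.0, 0.5)


@pytest.fixture(scope="session")
def parker(fine_times):
    """Parker population AIF with an 18 s bolus arrival."""
    return parker_aif(AifSpec(model_name="parker", onset_time=18.0), fine_times)


@pytest.fixture(scope="session")
def weinmann(fine_times):
    return weinmann_aif(AifSpec(model_name="weinmann", onset_time=18.0), fine_times)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def trapezoid_curve(times, t_onset, ttp, me, t_washout, irw):
    """Reference continuous piecewise-linear enhancement curve."""
    times = np.asarray(times, dtype=float)
    y = np.zeros_like(times)
    rise = (times > t_onset) & (times <= t_onset + ttp)
    y[rise] = me * (times[rise] - t_onset) / ttp
    plateau = (times > t_onset + ttp) & (times <= t_washout)
    y[plateau] = me
    wash = times > t_washout
    y[wash] = me + irw * (times[wash] - t_washout)
    return y
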