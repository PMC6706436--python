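import numpy as np
import pytest

from wilsonplan import CellParameters, get_space_group
from wilsonplan.shells import ResolutionShell, ShellSeries

TAURINE_CELL = CellParameters(5.2853, 11.6456, 7.9347, 90.0, 94.14, 90.0)
TAURINE_COMPOSITION = {"C": 8.0, "H": 28.0, "N": 4.0, "O": 12.0, "S": 4.0}


@pytest.fixture
def taurine_cell():
    return TAURINE_CELL


@pytest.fixture
def taurine_composition():
    return dict(TAURINE_COMPOSITION)


@pytest.fixture
def p21c():
    return get_space_group("P21/c")


def make_series(s_mids, S_values, width=0.005, n_obs=5):
    """Build a ShellSeries directly from (s_mid, S) pairs for estimator tests."""
    shells = []
    for i, (s, S) in enumerate(zip(s_mids, S_values)):
        shells.append(ResolutionShell(
            i, s - width / 2, s + width / 2, s, n_obs,
            mean_I=S, sum_f_sq=1.0, S=S))
    return ShellSeries(tuple(shells), width,
                       (s_mids[0] - width / 2, s_mids[-1] + width / 2))


@pytest.fixture
def two_shell_toy():
    """Noiseless S = exp(-2*2.0*s^2) at s = 0.2 and 0.4."""
    s = np.array([0.2, 0.4])
    return make_series(s, np.exp(-4.0 * s ** 2))
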