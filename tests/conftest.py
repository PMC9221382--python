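import numpy as np
import pytest

from ecisbarrier import DEFAULT_FREQUENCIES, default_naked, node_area_cm2

# printed two-phase worked example: plateau 8020 ohm, changepoint at 208
# cycles, decay 0.0107 per cycle toward the 1200-ohm cell-free level
WORKED = dict(r_plateau=8020.0, n_p1=208.0, lam=0.0107, r_f=1200.0)


@pytest.fixture(scope="session")
def naked():
    return default_naked()


@pytest.fixture(scope="session")
def freqs():
    return DEFAULT_FREQUENCIES


@pytest.fixture(scope="session")
def area():
    return node_area_cm2()


def tabulated_worked_example():
    """The printed Phase-2 expression tabulated at integer N in [209, 500]."""
    n = np.arange(209, 501, dtype=float)
    r = 6820.0 * np.exp(-0.0107 * (n - 208.0)) + 1200.0
    return n, r
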