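import numpy as np
import pytest

from racrho.model import (
    AbundanceVector, KineticParameters, build_network,
)


@pytest.fixture(scope="session")
def default_network():
    return build_network()


@pytest.fixture(scope="session")
def bistable_network():
    """Calibrated defaults at an inhibitor level inside the bistable window."""
    return build_network(u=2000.0)


@pytest.fixture(scope="session")
def zero_kinetics():
    """All rate constants zero (Michaelis constants kept positive)."""
    zeros = {n: 0.0 for n in KineticParameters().names}
    for km in ("rac_gef_km", "rac_gap_km", "rho_gef_km", "rho_gap_km",
               "pak_ptase_km", "gef_phos_km", "gef_ptase_km", "gap_act_km",
               "gap_deact_km"):
        zeros[km] = 1.0
    return KineticParameters(**zeros)


@pytest.fixture(scope="session")
def open_loop_kinetics():
    """Feedback loop cut (no RhoA->GAP arm): monostable at every dose."""
    return KineticParameters(gap_act_kcat=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_state_within(network, rng):
    """A random nonnegative state consistent with the network's totals."""
    from racrho.steady_state import _feasible_starts
    y = _feasible_starts(network, 1, int(rng.integers(0, 2**31)))[0]
    return network.full_state(y)
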