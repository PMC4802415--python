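import numpy as np
import pytest

from racrho.model import build_network
from racrho.protocol import (
    DoseSchedule, ProtocolParams, dose_response_hysteresis, make_schedule,
    run_protocol, untreated_steady_state,
)
from racrho.steady_state import find_steady_states, simulate


def test_naive_zero_dose_forcing_is_identically_zero():
    s = make_schedule("naive", 0.0)
    assert all(s.u(t) == 0.0 for t in np.linspace(0, 40, 9))


def test_washout_decay_closed_form():
    """u relaxes exponentially: 10 min after switching the applied dose to 0
    the residual is 2^(-10/t_half) of the level at the switch."""
    p = ProtocolParams(t_half=3.5, dose_max=1000.0)
    s = make_schedule("pretreated", 0.0, p)
    level = s.u(p.pretreat_duration)
    residual = s.u(p.pretreat_duration + 10.0)
    assert residual / level == pytest.approx(2 ** (-10 / 3.5), rel=1e-9)


def test_washout_residual_with_upper_half_life_is_exactly_25_percent():
    p = ProtocolParams(t_half=5.0, dose_max=1000.0)
    s = make_schedule("pretreated", 0.0, p)
    ratio = s.u(p.pretreat_duration + 10.0) / s.u(p.pretreat_duration)
    assert ratio == pytest.approx(0.25, rel=1e-9)


@pytest.mark.parametrize("bad", [
    lambda: make_schedule("naive", -1.0),
    lambda: make_schedule("soaked", 5.0),
    lambda: DoseSchedule([(0.0, 5.0)]),
    lambda: DoseSchedule([(10.0, -5.0)]),
])
def test_schedule_validation(bad):
    with pytest.raises(ValueError):
        bad()


def test_zero_schedule_returns_untreated_steady_state(default_network):
    s0 = untreated_steady_state(default_network)
    r = run_protocol(default_network, make_schedule("naive", 0.0), s0)
    assert r.rho_gtp == pytest.approx(s0[3], rel=1e-4)
    assert r.rac_gtp == pytest.approx(s0[1], rel=1e-4)


def test_long_constant_dose_arm_reaches_the_branch_steady_state(default_network):
    """A long incubation at a window dose lands exactly on the stable branch
    selected by the (low) initial condition."""
    p = ProtocolParams(naive_duration=2000.0)
    r = run_protocol(default_network, make_schedule("naive", 2000.0, p))
    ss = find_steady_states(default_network.with_u(2000.0), n_starts=16, seed=1)
    low = min((s for s in ss if s.label == "stable"), key=lambda s: s.state[3])
    assert r.rho_gtp == pytest.approx(low.state[3], rel=1e-4)
    assert r.rac_gtp == pytest.approx(low.state[1], rel=1e-4)


def test_instant_washout_limit_matches_piecewise_constant_dosing(default_network):
    """As t_half -> 0 the pretreated arm equals naive dosing applied to the
    state left by a constant-dose pretreat."""
    dose, p = 2000.0, ProtocolParams(t_half=1e-7)
    r = run_protocol(default_network, make_schedule("pretreated", dose, p))
    s0 = untreated_steady_state(default_network)
    _, traj1 = simulate(default_network.with_u(p.dose_max), s0,
                        t_end=p.pretreat_duration, tol=1e-8)
    _, traj2 = simulate(default_network.with_u(dose), traj1[-1],
                        t_end=p.post_duration, tol=1e-8)
    assert r.rho_gtp == pytest.approx(traj2[-1][3], rel=1e-3)


def test_subthreshold_pretreat_produces_no_gap(default_network):
    """With dose_max below the up-switch threshold the pretreat never flips
    the switch and the two arms coincide."""
    p = ProtocolParams(dose_max=1000.0)   # T1 is ~3550 nM
    doses = np.array([0.0, 300.0, 600.0, 1000.0])
    df, summary = dose_response_hysteresis(default_network, doses, p)
    assert not summary["hysteretic"]
    assert summary["max_abs_gap"] < 0.05 * default_network.abundances.rhoa_tot


def test_dose_response_hysteresis_at_calibrated_defaults(default_network):
    doses = np.array([0.0, 1000.0, 2000.0, 3000.0, 4500.0, 6000.0])
    df, summary = dose_response_hysteresis(default_network, doses)
    piv_rho = df.pivot(index="dose", columns="arm", values="rho_gtp")
    piv_rac = df.pivot(index="dose", columns="arm", values="rac_gtp")
    # pretreated RhoA sits at or above naive everywhere; Rac1 mirrors
    assert np.all(piv_rho["pretreated"] >= piv_rho["naive"] - 1e-3)
    assert np.all(piv_rac["pretreated"] <= piv_rac["naive"] + 1e-3)
    assert summary["hysteretic"]
    # both arms fully inhibited at the top dose
    top = piv_rho.loc[6000.0]
    assert abs(top["pretreated"] - top["naive"]) <= 0.01 * top["naive"]


def test_open_loop_gap_vanishes(open_loop_kinetics):
    net = build_network(kinetics=open_loop_kinetics)
    doses = np.array([0.0, 2000.0, 4000.0, 6000.0])
    _, summary = dose_response_hysteresis(net, doses)
    assert not summary["hysteretic"]


def test_dose_list_validation(default_network):
    with pytest.raises(ValueError, match="dose"):
        dose_response_hysteresis(default_network, np.array([0.0, 10.0, 20.0]))
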