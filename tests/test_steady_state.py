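import numpy as np
import pytest

from racrho.model import AbundanceVector, build_network
from racrho.steady_state import (
    RHS_TOL, classify_stability, dynamics_class, find_steady_states,
    reduced_jacobian, simulate, _feasible_starts, _odeint_relax, _polish,
)


def test_zero_kinetics_trajectory_is_constant(zero_kinetics):
    net = build_network(kinetics=zero_kinetics)
    x0 = net.inactive_state()
    _, traj = simulate(net, x0, t_end=50.0)
    assert np.allclose(traj, x0)


def test_zero_kinetics_single_start_is_marginal_fixed_point(zero_kinetics):
    net = build_network(kinetics=zero_kinetics)
    ss = find_steady_states(net, n_starts=1)
    assert len(ss) == 1
    assert ss[0].residual_norm == 0.0
    assert ss[0].label == "marginal"
    assert dynamics_class(net, n_starts=4) == "other"


def test_default_network_converges_from_inactive(default_network):
    _, traj = simulate(default_network, default_network.inactive_state(),
                       t_end=1e4, tol=1e-10)
    assert np.max(np.abs(default_network.rhs(traj[-1]))) < 1e-8


def test_three_fixed_points_inside_bistable_window(bistable_network):
    ss = find_steady_states(bistable_network, n_starts=20, seed=1)
    labels = sorted(s.label for s in ss)
    assert labels == ["stable", "stable", "unstable"]


def test_high_rhoa_state_has_lower_rac1(bistable_network):
    """The two stable states oppose each other: high RhoA pairs with low Rac1."""
    ss = find_steady_states(bistable_network, n_starts=20, seed=1)
    stables = [s.state for s in ss if s.label == "stable"]
    hi_rho = max(stables, key=lambda x: x[3])
    lo_rho = min(stables, key=lambda x: x[3])
    assert hi_rho[1] < lo_rho[1]


@pytest.mark.parametrize("trial", range(5))
def test_stable_set_matches_brute_force_integration(trial):
    """Multi-start fixed-point search vs long integrations from 40 starts."""
    rng = np.random.default_rng(500 + trial)
    ab = AbundanceVector(*rng.uniform(50, 1000, 5), racgap_tot=100.0)
    net = build_network(ab, None, u=float(rng.uniform(0, 2500)))
    found = [s.state for s in find_steady_states(net, n_starts=16, seed=1)
             if s.label == "stable"]
    ends = []
    for y0 in _feasible_starts(net, 40, seed=900 + trial):
        y = _polish(net, _odeint_relax(net, y0, 4000.0))
        if y is not None:
            x = net.full_state(y)
            if all(np.linalg.norm(x - e) > 1.0 for e in ends):
                ends.append(x)
    assert len(ends) == len(found)
    for x in ends:
        assert any(np.linalg.norm(x - f) < 1.0 for f in found)


def test_stable_state_returns_after_perturbation(bistable_network, rng):
    ss = find_steady_states(bistable_network, n_starts=20, seed=1)
    s = next(s for s in ss if s.label == "stable")
    x = s.state
    pert = x * (1.0 + 0.01 * rng.uniform(-1, 1, size=14))
    # re-project onto the original conservation totals via reduced coords
    y = bistable_network.reduced_state(pert)
    y_end = _odeint_relax(bistable_network, y, 3000.0)
    back = bistable_network.full_state(y_end)
    assert np.linalg.norm(back - x) < 1e-3 * np.linalg.norm(x)


def test_unstable_state_escapes_to_a_stable_state(bistable_network):
    ss = find_steady_states(bistable_network, n_starts=20, seed=1)
    saddle = next(s for s in ss if s.label == "unstable")
    stables = [s.state for s in ss if s.label == "stable"]
    escaped = False
    rng = np.random.default_rng(7)
    for _ in range(4):
        y = bistable_network.reduced_state(
            saddle.state * (1.0 + 0.01 * rng.uniform(-1, 1, size=14)))
        end = bistable_network.full_state(
            _odeint_relax(bistable_network, y, 4000.0))
        if any(np.linalg.norm(end - st) < 1e-2 * np.linalg.norm(st)
               for st in stables):
            escaped = True
            break
    assert escaped


def test_classify_stability_requires_a_steady_state(default_network):
    with pytest.raises(ValueError, match="not steady"):
        classify_stability(default_network, default_network.inactive_state())


def test_reduced_label_consistent_with_full_jacobian(bistable_network):
    """Stability does not depend on which variables conservation eliminates:
    the reduced leading eigenvalue matches the full 14x14 Jacobian spectrum
    after discarding the six conservation zero-modes."""
    ss = find_steady_states(bistable_network, n_starts=20, seed=1)
    for s in ss:
        x = s.state
        n = x.size
        jac = np.empty((n, n))
        for j in range(n):
            h = 1e-6 * max(abs(x[j]), 1.0)
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            jac[:, j] = (bistable_network._rhs_unchecked(xp)
                         - bistable_network._rhs_unchecked(xm)) / (2 * h)
        eigs = np.linalg.eigvals(jac)
        nonzero = sorted(eigs, key=lambda e: abs(e))[6:]   # drop 6 zero-modes
        lead_full = max(e.real for e in nonzero)
        assert np.sign(lead_full) == np.sign(s.leading_eig)
        assert lead_full == pytest.approx(s.leading_eig, rel=1e-3, abs=1e-8)


def test_dynamics_class_at_calibrated_defaults(default_network, bistable_network):
    assert dynamics_class(default_network, n_starts=12, seed=1) == "monostable"
    assert dynamics_class(bistable_network, n_starts=12, seed=1) == "bistable"
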