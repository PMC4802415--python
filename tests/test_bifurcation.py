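import numpy as np
import pytest

from racrho.bifurcation import (
    calibrate_bistable_defaults, hysteresis, refine_threshold, region2d,
    sweep1d,
)
from racrho.model import DEFAULT_KINETICS, build_network
from racrho.steady_state import dynamics_class, find_steady_states

U_GRID = np.linspace(0.0, 5000.0, 41)     # step 125 nM
RAC_GRID = np.linspace(1.0, 401.0, 41)    # step 10 nM


@pytest.fixture(scope="module")
def u_hyst(default_network):
    return hysteresis(default_network, "u", U_GRID)


@pytest.fixture(scope="module")
def u_hyst_rac(default_network):
    return hysteresis(default_network, "u", U_GRID, jump_readout="rac_gtp")


def test_single_point_sweep_is_a_steady_state(default_network):
    out = sweep1d(default_network, "u", np.array([500.0]))
    ss = find_steady_states(default_network.with_u(500.0), n_starts=12, seed=1)
    match = any(
        out["rho_gtp"][0] == pytest.approx(s.state[3], rel=1e-5, abs=1e-6)
        and out["rac_gtp"][0] == pytest.approx(s.state[1], rel=1e-5, abs=1e-6)
        for s in ss
    )
    assert match


def test_inhibitor_hysteresis_thresholds(u_hyst):
    assert u_hyst.bistable
    assert u_hyst.t2 < u_hyst.t1
    assert U_GRID[0] < u_hyst.t2 and u_hyst.t1 < U_GRID[-1]
    # regression against the calibrated defaults on this grid
    assert u_hyst.t1 == pytest.approx(3687.5)
    assert u_hyst.t2 == pytest.approx(437.5)


def test_forward_sweep_switches_rhoa_up(u_hyst):
    rho = u_hyst.forward["rho_gtp"]
    assert rho[0] < 20.0
    assert rho[-1] > 400.0


def test_rac_readout_jumps_at_same_doses_with_opposite_sign(u_hyst, u_hyst_rac):
    assert u_hyst_rac.bistable
    assert u_hyst_rac.t1 == pytest.approx(u_hyst.t1)
    assert u_hyst_rac.t2 == pytest.approx(u_hyst.t2)
    rac = u_hyst_rac.forward["rac_gtp"]
    rho = u_hyst.forward["rho_gtp"]
    assert rac[0] > rac[-1]          # Rac1 switches down as RhoA switches up
    assert rho[0] < rho[-1]


def test_branch_monotonicity_in_inhibitor(u_hyst):
    """RhoA-GTP rises monotonically along each stable branch, and the
    dominant Rac1-GTP change is the downward switch at the threshold.

    (Free Rac1-GTP may creep up slightly before the switch: inhibitor-bound
    PAK no longer sequesters Rac1-GTP in CRIB complexes.)
    """
    for branch in (u_hyst.forward, u_hyst.backward):
        rho, rac = branch["rho_gtp"], branch["rac_gtp"]
        jump = np.argmax(np.abs(np.diff(rho)))
        for seg in (slice(0, jump + 1), slice(jump + 1, None)):
            assert np.all(np.diff(rho[seg]) >= -1e-6)
        rac_drop = rac[jump] - rac[jump + 1]
        assert rac_drop > 0
        max_rise = np.diff(rac).max()
        assert max_rise < 0.2 * rac_drop


def test_high_rhoa_branch_has_lower_rac1_per_dose(u_hyst):
    """Anti-correlation: wherever the branches differ, the high-RhoA branch
    carries the lower Rac1-GTP."""
    fwd, bwd = u_hyst.forward, u_hyst.backward
    split = np.abs(fwd["rho_gtp"] - bwd["rho_gtp"]) > 50.0
    assert split.any()
    hi_is_bwd = bwd["rho_gtp"][split] > fwd["rho_gtp"][split]
    assert np.all(hi_is_bwd)
    assert np.all(bwd["rac_gtp"][split] < fwd["rac_gtp"][split])


def test_rac1_total_sweep_reproduces_hysteresis(default_network):
    h = hysteresis(default_network, "rac1_tot", RAC_GRID)
    assert h.bistable and h.t2 < h.t1
    # graded Rac1 increase pushes active RhoA from high to low
    assert h.forward["rho_gtp"][0] > 400.0
    assert h.forward["rho_gtp"][-1] < 20.0
    # backward traverse switches back up at the lower threshold
    assert h.backward["rho_gtp"][0] > 400.0


def test_monostable_kinetics_branches_coincide(open_loop_kinetics):
    net = build_network(kinetics=open_loop_kinetics)
    h = hysteresis(net, "u", U_GRID)
    assert not h.bistable
    assert h.t1 is None and h.t2 is None
    assert np.allclose(h.forward["rho_gtp"], h.backward["rho_gtp"],
                       rtol=1e-3, atol=1e-3)


def test_threshold_refinement_agrees_with_jump_location(default_network, u_hyst):
    step = U_GRID[1] - U_GRID[0]
    t1 = refine_threshold(default_network, "u", u_hyst.t1 - step,
                          u_hyst.t1 + step, n_starts=12, seed=1)
    assert abs(t1 - u_hyst.t1) <= step


def test_region2d_single_cell_equals_dynamics_class(default_network):
    rm = region2d(default_network, "rac1_tot", "rhoa_tot",
                  np.array([300.0]), np.array([700.0]), n_starts=8, seed=1)
    net = build_network(default_network.abundances.replace(
        rac1_tot=300.0, rhoa_tot=700.0), default_network.kinetics, 0.0)
    assert rm.labels[0, 0] == dynamics_class(net, n_starts=8, seed=1)


def test_hysteresis_requires_dense_grid(default_network):
    with pytest.raises(ValueError, match=">= 20"):
        hysteresis(default_network, "u", np.linspace(0, 4000, 10))


def test_calibration_returns_qualifying_midpoint_first():
    """The shipped defaults qualify, so a box centred on them returns them
    immediately even with max_iter=1."""
    box = {n: (0.5, 2.0) for n in DEFAULT_KINETICS.names}
    got = calibrate_bistable_defaults(
        box, build_network().abundances, np.linspace(0, 4000, 21),
        seed=1, max_iter=1, center=DEFAULT_KINETICS,
    )
    assert got == DEFAULT_KINETICS
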