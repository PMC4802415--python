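import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from racrho.model import (
    AbundanceVector, KineticParameters, MOIETIES, REACTIONS, SPECIES,
    ValidationError, build_network, moiety_totals,
)
from racrho.steady_state import simulate


def test_network_dimensions(default_network):
    assert len(SPECIES) == 14
    assert default_network.stoichiometry.shape == (14, 14)
    assert len(REACTIONS) == 14


def test_stoichiometry_conserves_every_moiety(default_network):
    prod = default_network.moiety_masks @ default_network.stoichiometry
    assert np.all(prod == 0)


@pytest.mark.parametrize("bad, err_field", [
    (dict(rac1_tot=-1.0), "rac1_tot"),
    (dict(pak_tot=float("nan")), "pak_tot"),
])
def test_abundance_validation_names_field(bad, err_field):
    with pytest.raises(ValidationError, match=err_field):
        AbundanceVector(**bad)


@pytest.mark.parametrize("bad, err_field", [
    (dict(rac_gef_km=0.0), "rac_gef_km"),
    (dict(pak_on=-0.1), "pak_on"),
])
def test_kinetics_validation_names_field(bad, err_field):
    with pytest.raises(ValidationError, match=err_field):
        KineticParameters(**bad)


def test_negative_inhibitor_rejected():
    with pytest.raises(ValidationError, match="u="):
        build_network(u=-5.0)


def test_zero_state_has_zero_derivative(default_network):
    # no zeroth-order production anywhere in the network
    assert np.all(default_network.rhs(np.zeros(14)) == 0.0)


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_rhs_lies_in_conservation_null_space(seed):
    """S v(x) is orthogonal to every moiety mask for arbitrary states."""
    net = build_network()
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 500.0, size=14)
    r = net.rhs(x)
    assert np.allclose(net.moiety_masks @ r, 0.0, atol=1e-9)


def test_rhs_rejects_invalid_states(default_network):
    with pytest.raises(ValidationError):
        default_network.rhs(np.full(14, -1.0))
    with pytest.raises(ValidationError):
        default_network.rhs(np.r_[np.nan, np.zeros(13)])
    with pytest.raises(ValidationError):
        default_network.rhs(np.zeros(5))


def test_single_reaction_hand_calculation():
    """With only PAK binding active, d(complex)/dt = kon * Rac1GTP * freePAK."""
    zeros = {n: 0.0 for n in KineticParameters().names}
    for km in ("rac_gef_km", "rac_gap_km", "rho_gef_km", "rho_gap_km",
               "pak_ptase_km", "gef_phos_km", "gef_ptase_km", "gap_act_km",
               "gap_deact_km"):
        zeros[km] = 1.0
    zeros["pak_on"] = 1.0
    net = build_network(kinetics=KineticParameters(**zeros))
    x = np.zeros(14)
    x[SPECIES.index("rac_gtp")] = 10.0
    x[SPECIES.index("pak_i")] = 20.0
    r = net.rhs(x)
    assert r[SPECIES.index("pak_rac")] == pytest.approx(1.0 * 10.0 * 20.0)
    assert r[SPECIES.index("rac_gtp")] == pytest.approx(-200.0)
    assert r[SPECIES.index("pak_i")] == pytest.approx(-200.0)


def test_moiety_totals_membership():
    assert moiety_totals(np.zeros(14)).as_array().tolist() == [0.0] * 6
    x = np.zeros(14)
    x[SPECIES.index("pak_rac")] = 5.0
    t = moiety_totals(x)
    assert t.rac1_tot == 5.0 and t.pak_tot == 5.0
    assert t.rhoa_tot == 0.0 and t.gefh1_tot == 0.0


def test_trajectory_conserves_moieties_and_nonnegativity(default_network):
    x0 = default_network.inactive_state()
    t, traj = simulate(default_network.with_u(800.0), x0, t_end=300.0,
                       tol=1e-8, t_eval=np.linspace(0, 300, 40))
    want = moiety_totals(x0).as_array()
    for x in traj:
        got = moiety_totals(x).as_array()
        assert np.all(np.abs(got - want) <= 1e-6 * np.maximum(want, 1.0))
    assert traj.min() > -1e-9


def test_rac_deactivation_flux_vanishes_without_gap():
    """With GAP off and no basal Rac GAP activity the deactivation rate is 0."""
    net = build_network(kinetics=KineticParameters(rac_gap_vmax=0.0))
    x = net.inactive_state()
    x[SPECIES.index("rac_gtp")] = 100.0
    x[SPECIES.index("gap_a")] = 0.0
    rates = net.rates(x)
    j = [name for name, _ in REACTIONS].index("rac_deact")
    assert rates[j] == 0.0


def test_yaml_config_roundtrip(tmp_path):
    from racrho.configio import load_config, save_config
    from racrho.protocol import ProtocolParams
    path = tmp_path / "model.yaml"
    ab = AbundanceVector(rac1_tot=321.0)
    kin = KineticParameters(pak_on=0.123)
    save_config(path, ab, kin, ProtocolParams(t_half=4.0), u=77.0)
    cfg = load_config(path)
    assert cfg["abundances"] == ab
    assert cfg["kinetics"] == kin
    assert cfg["u"] == 77.0
    assert cfg["protocol"].t_half == 4.0
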