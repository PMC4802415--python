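"""Kinetic model of the Rac1–RhoA–PAK double-negative feedback network.

The network couples two small-GTPase activation cycles through a pair of
inhibitory arms.  Rac1-GTP binds PAK at its CRIB domain; the complex
autophosphorylates to active PAK (pPAK), which phosphorylates the RhoA GEF
GEF-H1 on inhibitory sites.  Phospho-GEF-H1 is sequestered by 14-3-3, which
shuts down RhoA activation.  Conversely RhoA-GTP activates Rac1 GAPs (the
ROCK→GAP arm lumped into one activation step), which deactivate Rac1.  A
small-molecule PAK inhibitor binds inactive PAK, competing with Rac1-GTP
binding; its free intracellular concentration ``u`` is an external forcing,
not a conserved species.

Fourteen molecular species, fourteen reactions, six conserved moieties
(Rac1, RhoA, PAK, GEF-H1, 14-3-3, RacGAP).  Units are nM and minutes
throughout.  Rate laws combine mass action (binding steps) and
Michaelis–Menten kinetics (enzymatic interconversions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import numpy as np

__all__ = [
    "SPECIES",
    "MOIETIES",
    "AbundanceVector",
    "KineticParameters",
    "ReactionNetwork",
    "build_network",
    "rhs",
    "moiety_totals",
    "DEFAULT_ABUNDANCES",
    "DEFAULT_KINETICS",
]

#: Fixed species order, also the column order of every CSV the package writes.
SPECIES: tuple[str, ...] = (
    "rac_gdp",      # Rac1-GDP (inactive)
    "rac_gtp",      # Rac1-GTP (active)
    "rho_gdp",      # RhoA-GDP (inactive)
    "rho_gtp",      # RhoA-GTP (active)
    "pak_i",        # inactive, unphosphorylated PAK
    "pak_rac",      # Rac1-GTP:PAK complex (CRIB-bound)
    "pak_p",        # autophosphorylated, active PAK
    "pak_inh",      # inhibitor-bound inactive PAK
    "gef",          # active (unphosphorylated) GEF-H1
    "gef_p",        # phospho-GEF-H1 (inactivated)
    "gef_p_1433",   # phospho-GEF-H1 : 14-3-3 complex (sequestered)
    "f1433",        # free 14-3-3
    "gap_i",        # inactive Rac1 GAP
    "gap_a",        # active Rac1 GAP
)

N_SPECIES = len(SPECIES)
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: Conserved-moiety membership masks over the species order above.
MOIETIES: dict[str, tuple[str, ...]] = {
    "rac1_tot": ("rac_gdp", "rac_gtp", "pak_rac"),
    "rhoa_tot": ("rho_gdp", "rho_gtp"),
    "pak_tot": ("pak_i", "pak_rac", "pak_p", "pak_inh"),
    "gefh1_tot": ("gef", "gef_p", "gef_p_1433"),
    "s1433_tot": ("f1433", "gef_p_1433"),
    "racgap_tot": ("gap_i", "gap_a"),
}


def _moiety_masks() -> np.ndarray:
    m = np.zeros((len(MOIETIES), N_SPECIES))
    for row, members in enumerate(MOIETIES.values()):
        for s in members:
            m[row, _IDX[s]] = 1.0
    return m


_MASKS = _moiety_masks()

# Reaction catalogue: name -> net stoichiometry.  Reversible binding steps
# (PAK:Rac1-GTP, 14-3-3 sequestration) are single net-rate columns; inhibitor
# binding and unbinding are separate columns.
REACTIONS: tuple[tuple[str, dict[str, int]], ...] = (
    ("rac_act", {"rac_gdp": -1, "rac_gtp": +1}),
    ("rac_deact", {"rac_gtp": -1, "rac_gdp": +1}),
    ("rho_act", {"rho_gdp": -1, "rho_gtp": +1}),
    ("rho_deact", {"rho_gtp": -1, "rho_gdp": +1}),
    ("pak_bind", {"rac_gtp": -1, "pak_i": -1, "pak_rac": +1}),
    ("pak_autophos", {"pak_rac": -1, "pak_p": +1, "rac_gtp": +1}),
    ("pak_dephos", {"pak_p": -1, "pak_i": +1}),
    ("gef_phos", {"gef": -1, "gef_p": +1}),
    ("gef_dephos", {"gef_p": -1, "gef": +1}),
    ("seq_bind", {"gef_p": -1, "f1433": -1, "gef_p_1433": +1}),
    ("gap_act", {"gap_i": -1, "gap_a": +1}),
    ("gap_deact", {"gap_a": -1, "gap_i": +1}),
    ("inh_bind", {"pak_i": -1, "pak_inh": +1}),
    ("inh_unbind", {"pak_inh": -1, "pak_i": +1}),
)


def _stoichiometry() -> np.ndarray:
    s = np.zeros((N_SPECIES, len(REACTIONS)))
    for j, (_, stoich) in enumerate(REACTIONS):
        for name, coeff in stoich.items():
            s[_IDX[name], j] = coeff
    return s


_STOICH = _stoichiometry()


class ValidationError(ValueError):
    """A field of an input structure violates its constraints."""


@dataclass(frozen=True)
class AbundanceVector:
    """Total concentrations (nM) of the six conserved moieties.

    Five of the six (Rac1, RhoA, PAK, GEF-H1, 14-3-3) are the axes sampled
    in abundance-space scans; the RacGAP total is a model-internal moiety
    kept at a fixed default because the RhoA→GAP arm lumps ROCK-mediated
    GAP activation into one step.
    """

    rac1_tot: float = 600.0
    rhoa_tot: float = 550.0
    pak_tot: float = 550.0
    gefh1_tot: float = 100.0
    s1433_tot: float = 650.0
    racgap_tot: float = 100.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"abundance {f.name}={v!r} must be finite and >= 0"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    def replace(self, **kw) -> "AbundanceVector":
        d = asdict(self)
        d.update(kw)
        return AbundanceVector(**d)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self))


# Km fields must be strictly positive wherever a Michaelis-Menten law uses them.
_KM_FIELDS = (
    "rac_gef_km", "rac_gap_km", "rho_gef_km", "rho_gap_km",
    "pak_ptase_km", "gef_phos_km", "gef_ptase_km", "gap_act_km",
    "gap_deact_km",
)


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the fourteen reactions.

    on/off rates in nM^-1 min^-1 and min^-1, catalytic constants kcat in
    min^-1, Michaelis constants Km in nM, basal Vmax terms in nM min^-1.
    Defaults are the calibrated bistable reference set (see
    :data:`DEFAULT_KINETICS`).
    """

    # Rac1 activation (basal Rac GEF) and deactivation (GAP-driven + basal)
    rac_gef_vmax: float = 350.0
    rac_gef_km: float = 676.0
    rac_gap_kcat: float = 7.5
    rac_gap_vmax: float = 23.3
    rac_gap_km: float = 134.0
    # RhoA activation (GEF-H1-driven + basal) and deactivation (basal Rho GAP)
    rho_gef_kcat: float = 20.4
    rho_gef_vmax: float = 7.62
    rho_gef_km: float = 91.6
    rho_gap_vmax: float = 792.0
    rho_gap_km: float = 249.0
    # PAK activation: Rac1-GTP binding, intramolecular autophosphorylation,
    # and dephosphorylation back to the closed conformation
    pak_on: float = 0.0392
    pak_off: float = 10.0
    pak_auto_k: float = 6.78
    pak_ptase_vmax: float = 708.0
    pak_ptase_km: float = 42.6
    # GEF-H1 phosphorylation by pPAK on inhibitory sites, and its reversal
    gef_phos_kcat: float = 6.78
    gef_phos_km: float = 8.48
    gef_ptase_vmax: float = 2260.0
    gef_ptase_km: float = 3.71
    # 14-3-3 sequestration of phospho-GEF-H1
    seq_on: float = 1.25
    seq_off: float = 0.509
    # RhoA-GTP-driven Rac1 GAP activation and its decay
    gap_act_kcat: float = 0.208
    gap_act_km: float = 15.4
    gap_deact_vmax: float = 21.4
    gap_deact_km: float = 5.52
    # PAK inhibitor binding to inactive PAK (competes with Rac1-GTP binding)
    inh_on: float = 0.0612
    inh_off: float = 9.48

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"kinetic constant {f.name}={v!r} must be finite and >= 0"
                )
        for name in _KM_FIELDS:
            if getattr(self, name) <= 0:
                raise ValidationError(
                    f"Michaelis constant {name} must be > 0 (got "
                    f"{getattr(self, name)!r})"
                )

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def replace(self, **kw) -> "KineticParameters":
        d = asdict(self)
        d.update(kw)
        return KineticParameters(**d)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self))


# Reduced coordinates: conservation eliminates one species per moiety.
#: Free (retained) species of the conservation-reduced system, in order.
FREE_SPECIES: tuple[str, ...] = (
    "rac_gtp", "rho_gtp", "pak_rac", "pak_p", "pak_inh",
    "gef_p", "gef_p_1433", "gap_a",
)
_FREE_IDX = np.array([_IDX[s] for s in FREE_SPECIES])


@dataclass
class ReactionNetwork:
    """A parameterized instance of the reaction network.

    Bundles total abundances, kinetic constants and the clamped free
    inhibitor concentration ``u`` with the (validated) stoichiometry matrix
    and precomputed moiety masks.
    """

    abundances: AbundanceVector
    kinetics: KineticParameters
    u: float = 0.0
    stoichiometry: np.ndarray = field(default_factory=lambda: _STOICH.copy())
    moiety_masks: np.ndarray = field(default_factory=lambda: _MASKS.copy())

    def __post_init__(self) -> None:
        if not np.isfinite(self.u) or self.u < 0:
            raise ValidationError(f"inhibitor level u={self.u!r} must be finite and >= 0")
        # stoichiometry must conserve every moiety
        if not np.allclose(self.moiety_masks @ self.stoichiometry, 0.0):
            raise ValidationError("stoichiometry does not conserve all moieties")

    # -- rate laws ---------------------------------------------------------

    def rates(self, state: np.ndarray, u: float | None = None) -> np.ndarray:
        """Rate-law vector v(state) in nM/min, one entry per reaction column."""
        k = self.kinetics
        if u is None:
            u = self.u
        (rac_gdp, rac_gtp, rho_gdp, rho_gtp, pak_i, pak_rac, pak_p, pak_inh,
         gef, gef_p, gef_p_1433, f1433, gap_i, gap_a) = state
        return np.array([
            k.rac_gef_vmax * rac_gdp / (k.rac_gef_km + rac_gdp),
            (k.rac_gap_kcat * gap_a + k.rac_gap_vmax)
            * rac_gtp / (k.rac_gap_km + rac_gtp),
            (k.rho_gef_kcat * gef + k.rho_gef_vmax)
            * rho_gdp / (k.rho_gef_km + rho_gdp),
            k.rho_gap_vmax * rho_gtp / (k.rho_gap_km + rho_gtp),
            k.pak_on * rac_gtp * pak_i - k.pak_off * pak_rac,
            k.pak_auto_k * pak_rac,
            k.pak_ptase_vmax * pak_p / (k.pak_ptase_km + pak_p),
            k.gef_phos_kcat * pak_p * gef / (k.gef_phos_km + gef),
            k.gef_ptase_vmax * gef_p / (k.gef_ptase_km + gef_p),
            k.seq_on * gef_p * f1433 - k.seq_off * gef_p_1433,
            k.gap_act_kcat * rho_gtp * gap_i / (k.gap_act_km + gap_i),
            k.gap_deact_vmax * gap_a / (k.gap_deact_km + gap_a),
            k.inh_on * u * pak_i,
            k.inh_off * pak_inh,
        ])

    def rhs(self, state: np.ndarray, u: float | None = None) -> np.ndarray:
        """Time derivative S·v(state) of the full 14-species state (nM/min)."""
        state = np.asarray(state, dtype=float)
        if state.shape != (N_SPECIES,):
            raise ValidationError(
                f"state must have {N_SPECIES} entries, got shape {state.shape}"
            )
        if np.any(~np.isfinite(state)) or np.any(state < 0):
            raise ValidationError("state concentrations must be finite and >= 0")
        return self.stoichiometry @ self.rates(state, u)

    def _rhs_unchecked(self, state: np.ndarray, u: float | None = None) -> np.ndarray:
        return self.stoichiometry @ self.rates(state, u)

    # -- conservation-reduced coordinates ---------------------------------

    def full_state(self, y: np.ndarray) -> np.ndarray:
        """Reconstruct the 14-species state from the 8 free coordinates."""
        a = self.abundances
        rac_gtp, rho_gtp, pak_rac, pak_p, pak_inh, gef_p, gef_p_1433, gap_a = y
        x = np.empty(N_SPECIES)
        x[_IDX["rac_gtp"]] = rac_gtp
        x[_IDX["rho_gtp"]] = rho_gtp
        x[_IDX["pak_rac"]] = pak_rac
        x[_IDX["pak_p"]] = pak_p
        x[_IDX["pak_inh"]] = pak_inh
        x[_IDX["gef_p"]] = gef_p
        x[_IDX["gef_p_1433"]] = gef_p_1433
        x[_IDX["gap_a"]] = gap_a
        x[_IDX["rac_gdp"]] = a.rac1_tot - rac_gtp - pak_rac
        x[_IDX["rho_gdp"]] = a.rhoa_tot - rho_gtp
        x[_IDX["pak_i"]] = a.pak_tot - pak_rac - pak_p - pak_inh
        x[_IDX["gef"]] = a.gefh1_tot - gef_p - gef_p_1433
        x[_IDX["f1433"]] = a.s1433_tot - gef_p_1433
        x[_IDX["gap_i"]] = a.racgap_tot - gap_a
        return x

    def reduced_state(self, state: np.ndarray) -> np.ndarray:
        return np.asarray(state, dtype=float)[_FREE_IDX]

    def rhs_reduced(self, y: np.ndarray, u: float | None = None) -> np.ndarray:
        """Right-hand side of the 8-dimensional conservation-reduced system."""
        return self._rhs_unchecked(self.full_state(y), u)[_FREE_IDX]

    # -- convenience states ------------------------------------------------

    def inactive_state(self) -> np.ndarray:
        """All moieties in their inactive/unbound forms."""
        a = self.abundances
        x = np.zeros(N_SPECIES)
        x[_IDX["rac_gdp"]] = a.rac1_tot
        x[_IDX["rho_gdp"]] = a.rhoa_tot
        x[_IDX["pak_i"]] = a.pak_tot
        x[_IDX["gef"]] = a.gefh1_tot
        x[_IDX["f1433"]] = a.s1433_tot
        x[_IDX["gap_i"]] = a.racgap_tot
        return x

    def active_state(self) -> np.ndarray:
        """GTPases GTP-loaded, PAK phosphorylated, GEF-H1 sequestered, GAP on."""
        a = self.abundances
        x = np.zeros(N_SPECIES)
        x[_IDX["rac_gtp"]] = a.rac1_tot
        x[_IDX["rho_gtp"]] = a.rhoa_tot
        x[_IDX["pak_p"]] = a.pak_tot
        seq = min(a.gefh1_tot, a.s1433_tot)
        x[_IDX["gef_p_1433"]] = seq
        x[_IDX["gef_p"]] = a.gefh1_tot - seq
        x[_IDX["f1433"]] = a.s1433_tot - seq
        x[_IDX["gap_a"]] = a.racgap_tot
        return x

    def with_u(self, u: float) -> "ReactionNetwork":
        return ReactionNetwork(self.abundances, self.kinetics, u)

    def with_abundances(self, abundances: AbundanceVector) -> "ReactionNetwork":
        return ReactionNetwork(abundances, self.kinetics, self.u)


def build_network(
    abundances: AbundanceVector | None = None,
    kinetics: KineticParameters | None = None,
    u: float = 0.0,
) -> ReactionNetwork:
    """Assemble and validate a :class:`ReactionNetwork`.

    Raises :class:`ValidationError` (naming the offending field) for
    negative or non-finite abundances, kinetic constants or inhibitor level.
    """
    if abundances is None:
        abundances = DEFAULT_ABUNDANCES
    if kinetics is None:
        kinetics = DEFAULT_KINETICS
    return ReactionNetwork(abundances, kinetics, u)


def rhs(state: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Functional form of :meth:`ReactionNetwork.rhs`."""
    return network.rhs(state)


def moiety_totals(state: np.ndarray) -> AbundanceVector:
    """Sum each conserved moiety over its member species."""
    state = np.asarray(state, dtype=float)
    sums = _MASKS @ state
    return AbundanceVector(**dict(zip(MOIETIES.keys(), sums)))


#: Default abundances: values inside the 0–1,000 nM sampling box used for
#: abundance-space analysis, chosen so the two inhibitory arms are balanced.
#: Substitute measured totals for a specific cell line via configuration.
DEFAULT_ABUNDANCES = AbundanceVector()

#: Calibrated reference kinetics: the first parameter set found by
#: ``bifurcation.calibrate_bistable_defaults`` (seed 1, shipped search box)
#: whose inhibitor dose response is hysteretic at the default abundances.
#: These are model-internal calibrated values, not measured constants.
DEFAULT_KINETICS = KineticParameters()
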