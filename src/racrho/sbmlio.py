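"""SBML Level 3 export/import of the reaction network.

The writer emits a self-contained SBML L3V2 document (species with initial
concentrations, global parameters, reactions with full MathML kinetic laws)
so the model can be exchanged with standard systems-biology tooling.  The
reader reconstructs a :class:`ReactionNetwork` from the document's species
and parameter values, keyed by the fixed reaction catalogue; a round trip
reproduces the right-hand side exactly.

Rate laws are written from a small expression AST (`RATE_EXPRS`) that is
kept in lockstep with the rate functions in :mod:`racrho.model`; the test
suite evaluates the AST against the model on random states.
"""

from __future__ import annotations

import numpy as np
from lxml import etree

from .model import (
    KineticParameters, REACTIONS, ReactionNetwork, SPECIES, build_network,
    moiety_totals,
)

__all__ = ["export_sbml", "import_sbml", "write_sbml", "read_sbml", "RATE_EXPRS"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

# expression AST per reaction: ("op", args...) with op in {+,-,*,/},
# leaves are species/parameter ids (str) or numbers
RATE_EXPRS: dict[str, tuple] = {
    "rac_act": ("/", ("*", "rac_gef_vmax", "rac_gdp"),
                ("+", "rac_gef_km", "rac_gdp")),
    "rac_deact": ("/", ("*", ("+", ("*", "rac_gap_kcat", "gap_a"),
                              "rac_gap_vmax"), "rac_gtp"),
                  ("+", "rac_gap_km", "rac_gtp")),
    "rho_act": ("/", ("*", ("+", ("*", "rho_gef_kcat", "gef"),
                            "rho_gef_vmax"), "rho_gdp"),
                ("+", "rho_gef_km", "rho_gdp")),
    "rho_deact": ("/", ("*", "rho_gap_vmax", "rho_gtp"),
                  ("+", "rho_gap_km", "rho_gtp")),
    "pak_bind": ("-", ("*", "pak_on", "rac_gtp", "pak_i"),
                 ("*", "pak_off", "pak_rac")),
    "pak_autophos": ("*", "pak_auto_k", "pak_rac"),
    "pak_dephos": ("/", ("*", "pak_ptase_vmax", "pak_p"),
                   ("+", "pak_ptase_km", "pak_p")),
    "gef_phos": ("/", ("*", "gef_phos_kcat", "pak_p", "gef"),
                 ("+", "gef_phos_km", "gef")),
    "gef_dephos": ("/", ("*", "gef_ptase_vmax", "gef_p"),
                   ("+", "gef_ptase_km", "gef_p")),
    "seq_bind": ("-", ("*", "seq_on", "gef_p", "f1433"),
                 ("*", "seq_off", "gef_p_1433")),
    "gap_act": ("/", ("*", "gap_act_kcat", "rho_gtp", "gap_i"),
                ("+", "gap_act_km", "gap_i")),
    "gap_deact": ("/", ("*", "gap_deact_vmax", "gap_a"),
                  ("+", "gap_deact_km", "gap_a")),
    "inh_bind": ("*", "inh_on", "u_inhibitor", "pak_i"),
    "inh_unbind": ("*", "inh_off", "pak_inh"),
}

_OPS = {"+": "plus", "-": "minus", "*": "times", "/": "divide"}


def eval_expr(expr, env: dict[str, float]) -> float:
    """Evaluate a rate-expression AST in an environment (used by tests)."""
    if isinstance(expr, str):
        return env[expr]
    if isinstance(expr, (int, float)):
        return float(expr)
    op, *args = expr
    vals = [eval_expr(a, env) for a in args]
    if op == "+":
        return sum(vals)
    if op == "-":
        return vals[0] - sum(vals[1:])
    if op == "*":
        return float(np.prod(vals))
    if op == "/":
        return vals[0] / vals[1]
    raise ValueError(f"unknown op {op}")


def _mathml(expr, parent) -> None:
    m = "{%s}" % MATHML_NS
    if isinstance(expr, str):
        ci = etree.SubElement(parent, m + "ci")
        ci.text = f" {expr} "
        return
    if isinstance(expr, (int, float)):
        cn = etree.SubElement(parent, m + "cn")
        cn.text = f" {expr} "
        return
    op, *args = expr
    apply_ = etree.SubElement(parent, m + "apply")
    etree.SubElement(apply_, m + _OPS[op])
    for a in args:
        _mathml(a, apply_)


def export_sbml(network: ReactionNetwork, state0: np.ndarray | None = None) -> bytes:
    """Serialize the network as an SBML L3V2 document (UTF-8 bytes).

    ``state0`` sets the species initial concentrations; defaults to the
    all-inactive configuration consistent with the network's totals.
    """
    if state0 is None:
        state0 = network.inactive_state()
    state0 = np.asarray(state0, dtype=float)
    got = moiety_totals(state0).as_array()
    want = network.abundances.as_array()
    denom = np.maximum(want, 1.0)
    if np.any(np.abs(got - want) / denom > 1e-6):
        raise ValueError("state0 moiety totals do not match the network")

    s = "{%s}" % SBML_NS
    root = etree.Element(s + "sbml", nsmap={None: SBML_NS},
                         attrib={"level": "3", "version": "2"})
    model = etree.SubElement(root, s + "model", id="rac1_rhoa_pak",
                             substanceUnits="nanomole", timeUnits="minute")
    comps = etree.SubElement(model, s + "listOfCompartments")
    etree.SubElement(comps, s + "compartment", id="cell", size="1",
                     constant="true", spatialDimensions="3")
    sp_list = etree.SubElement(model, s + "listOfSpecies")
    for name, conc in zip(SPECIES, state0):
        etree.SubElement(
            sp_list, s + "species", id=name, compartment="cell",
            initialConcentration=repr(float(conc)),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false",
        )
    par_list = etree.SubElement(model, s + "listOfParameters")
    for pname, pval in network.kinetics.as_dict().items():
        etree.SubElement(par_list, s + "parameter", id=pname,
                         value=repr(float(pval)), constant="true")
    # clamped external forcing: constant within a document
    etree.SubElement(par_list, s + "parameter", id="u_inhibitor",
                     value=repr(float(network.u)), constant="true")
    rx_list = etree.SubElement(model, s + "listOfReactions")
    for rname, stoich in REACTIONS:
        rx = etree.SubElement(rx_list, s + "reaction", id=rname,
                              reversible=str(rname in ("pak_bind", "seq_bind")).lower())
        reactants = {k: -v for k, v in stoich.items() if v < 0}
        products = {k: v for k, v in stoich.items() if v > 0}
        if reactants:
            rl = etree.SubElement(rx, s + "listOfReactants")
            for sp, coeff in reactants.items():
                etree.SubElement(rl, s + "speciesReference", species=sp,
                                 stoichiometry=str(coeff), constant="true")
        if products:
            pl = etree.SubElement(rx, s + "listOfProducts")
            for sp, coeff in products.items():
                etree.SubElement(pl, s + "speciesReference", species=sp,
                                 stoichiometry=str(coeff), constant="true")
        kl = etree.SubElement(rx, s + "kineticLaw")
        math = etree.SubElement(kl, "{%s}math" % MATHML_NS,
                                nsmap={None: MATHML_NS})
        _mathml(RATE_EXPRS[rname], math)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def import_sbml(document: bytes | str) -> tuple[ReactionNetwork, np.ndarray]:
    """Rebuild (network, initial state) from a document written by
    :func:`export_sbml`.  Raises on missing species, parameters or unknown
    reactions."""
    if isinstance(document, str):
        document = document.encode()
    root = etree.fromstring(document)
    ns = {"s": SBML_NS}
    conc = {}
    for sp in root.findall(".//s:listOfSpecies/s:species", ns):
        conc[sp.get("id")] = float(sp.get("initialConcentration"))
    missing = [n for n in SPECIES if n not in conc]
    if missing:
        raise ValueError(f"document lacks species {missing}")
    state0 = np.array([conc[n] for n in SPECIES])

    pvals = {}
    for p in root.findall(".//s:listOfParameters/s:parameter", ns):
        pvals[p.get("id")] = float(p.get("value"))
    u = pvals.pop("u_inhibitor", 0.0)
    known = set(KineticParameters().names)
    extra = set(pvals) - known
    if extra:
        raise ValueError(f"unknown parameters {sorted(extra)}")
    kinetics = KineticParameters(**pvals)

    rx_ids = [r.get("id") for r in root.findall(".//s:listOfReactions/s:reaction", ns)]
    expected = [name for name, _ in REACTIONS]
    if rx_ids != expected:
        raise ValueError("reaction catalogue mismatch with this model")
    abundances = moiety_totals(state0)
    return build_network(abundances, kinetics, u=u), state0


def write_sbml(network: ReactionNetwork, path, state0=None) -> None:
    with open(path, "wb") as fh:
        fh.write(export_sbml(network, state0))


def read_sbml(path) -> tuple[ReactionNetwork, np.ndarray]:
    with open(path, "rb") as fh:
        return import_sbml(fh.read())
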