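"""YAML model configuration: abundances, kinetics, protocol constants."""

from __future__ import annotations

import yaml

from .model import AbundanceVector, KineticParameters, ReactionNetwork, build_network
from .protocol import ProtocolParams

__all__ = ["load_config", "save_config", "network_from_config"]


def save_config(path, abundances: AbundanceVector | None = None,
                kinetics: KineticParameters | None = None,
                protocol: ProtocolParams | None = None,
                u: float = 0.0) -> None:
    doc = {
        "abundances_nM": dict(
            zip((abundances or AbundanceVector()).names,
                map(float, (abundances or AbundanceVector()).as_array()))),
        "kinetics": {k: float(v) for k, v in
                     (kinetics or KineticParameters()).as_dict().items()},
        "inhibitor_nM": float(u),
        "protocol": vars(protocol or ProtocolParams()),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    out["abundances"] = AbundanceVector(**doc.get("abundances_nM", {}))
    out["kinetics"] = KineticParameters(**doc.get("kinetics", {}))
    out["u"] = float(doc.get("inhibitor_nM", 0.0))
    out["protocol"] = ProtocolParams(**doc.get("protocol", {}))
    return out


def network_from_config(path) -> ReactionNetwork:
    cfg = load_config(path)
    return build_network(cfg["abundances"], cfg["kinetics"], cfg["u"])
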