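#!/usr/bin/env python
"""Inhibitor and Rac1-abundance hysteresis sweeps at the calibrated defaults.

Writes one tidy CSV row per grid point per sweep direction per readout and
prints the saddle-node thresholds (T1 up-switch, T2 down-switch).
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from racrho.bifurcation import hysteresis
from racrho.model import build_network

parser = argparse.ArgumentParser()
parser.add_argument("--out-dir", default="results")
args = parser.parse_args()
out = Path(args.out_dir)
out.mkdir(exist_ok=True)

net = build_network()
rows = []
for param, grid in [("u", np.linspace(0.0, 5000.0, 41)),
                    ("rac1_tot", np.linspace(1.0, 401.0, 41))]:
    h = hysteresis(net, param, grid)
    print(f"{param}: bistable={h.bistable}  T1={h.t1:.2f}  T2={h.t2:.2f} nM")
    for direction, branch in [("forward", h.forward), ("backward", h.backward)]:
        for readout, values in branch.items():
            for g, v in zip(grid, values):
                rows.append({"param": param, "direction": direction,
                             "readout": readout, "value_nM": v, "grid_nM": g})

pd.DataFrame(rows).to_csv(out / "hysteresis_sweeps.csv", index=False)
print(f"wrote {out/'hysteresis_sweeps.csv'} ({len(rows)} rows)")
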