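#!/usr/bin/env python
"""Confirm the shipped default kinetics qualify as a bistable calibration.

The packaged defaults were produced by the random-search calibrator; this
driver re-runs the calibrator with the shipped search box (centred on the
defaults) and records the qualifying set and its inhibitor thresholds.
"""

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from racrho.bifurcation import DEFAULT_KINETICS_BOX, calibrate_bistable_defaults, hysteresis
from racrho.configio import save_config
from racrho.model import DEFAULT_ABUNDANCES, DEFAULT_KINETICS, build_network

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", default="results")
args = parser.parse_args()

u_grid = np.linspace(0.0, 5000.0, 41)
kin = calibrate_bistable_defaults(
    DEFAULT_KINETICS_BOX, DEFAULT_ABUNDANCES, u_grid, seed=args.seed,
    center=DEFAULT_KINETICS,
)
assert kin == DEFAULT_KINETICS, "shipped defaults should qualify immediately"

h = hysteresis(build_network(DEFAULT_ABUNDANCES, kin, 0.0), "u", u_grid)
out = Path(args.out_dir)
out.mkdir(exist_ok=True)
save_config(out / "calibrated_model.yaml", DEFAULT_ABUNDANCES, kin)
print(f"calibrated kinetics written to {out/'calibrated_model.yaml'}")
print(f"inhibitor dose response is hysteretic: T1={h.t1:.1f} nM, "
      f"T2={h.t2:.1f} nM (width {h.t1-h.t2:.1f} nM)")
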