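#!/usr/bin/env python
"""Two-parameter stability map over Rac1 and RhoA total abundances."""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from racrho.bifurcation import region2d
from racrho.model import build_network

parser = argparse.ArgumentParser()
parser.add_argument("--points", type=int, default=20)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", default="results")
args = parser.parse_args()
out = Path(args.out_dir)
out.mkdir(exist_ok=True)

centers = np.linspace(25.0, 975.0, args.points)
rm = region2d(build_network(), "rac1_tot", "rhoa_tot", centers, centers,
              n_starts=8, seed=args.seed)
rows = [{"rac1_tot": x, "rhoa_tot": y, "label": rm.labels[i, j]}
        for i, y in enumerate(centers) for j, x in enumerate(centers)]
df = pd.DataFrame(rows)
df.to_csv(out / "region_map.csv", index=False)
counts = df["label"].value_counts().to_dict()
print(f"{args.points}x{args.points} map over [0,1000] nM^2: {counts}")
print(f"wrote {out/'region_map.csv'}")
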