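# racrho — bistability in the Rac1–RhoA–PAK signaling switch

The small GTPases Rac1 and RhoA organize opposite sides of a migrating
cell: Rac1 drives lamellipodial protrusion at the front, RhoA drives
actomyosin contraction at the rear. Biochemically they suppress each
other through a double-negative feedback loop — Rac1-GTP activates PAK,
which phosphorylates and (via 14-3-3 sequestration) inactivates the RhoA
GEF GEF-H1, while RhoA-GTP activates Rac1 GAPs through the ROCK axis.
Mutual inhibition of this kind can make the network **bistable**: at the
same inputs, a cell can rest in either a high-Rac1/low-RhoA state or a
low-Rac1/high-RhoA state, with switch-like, hysteretic transitions
between them.

`racrho` is a kinetic model of this circuit together with the full
analysis pipeline needed to characterize its switch behavior:

* **Model** (`racrho.model`): 14 species, 14 mass-action /
  Michaelis–Menten reactions, 6 conserved moieties (Rac1, RhoA, PAK,
  GEF-H1, 14-3-3, RacGAP totals), with a clamped free-inhibitor forcing
  `u` describing a small-molecule PAK inhibitor that binds inactive PAK
  in competition with Rac1-GTP. Units: nM, minutes. SBML L3 export/import
  and YAML configuration included.
* **Steady states** (`racrho.steady_state`): stiff simulation,
  multi-start fixed-point location on the conservation-reduced system,
  Jacobian stability labels, and a monostable/bistable/other classifier.
* **Bifurcation analysis** (`racrho.bifurcation`): carry-over-continuation
  parameter sweeps with up/down switch thresholds T1/T2, two-parameter
  stability region maps, and the random-search calibrator that produced
  the shipped default kinetics.
* **Abundance-space scans** (`racrho.parameter_space`): random 5D
  sampling of protein totals, per-set classification, association
  contrasts and parallel-coordinate tables.
* **Dosing protocols** (`racrho.protocol`): naive dosing versus
  pretreat/washout schedules with first-order intracellular inhibitor
  kinetics (washout half-life 3.5 min by default).
* **Synthetic single-cell populations** (`racrho.population`): lognormal
  cell-to-cell abundance variability, noisy readouts, a mixture-based
  bimodality test (with a dip statistic as secondary evidence), and a
  parameter-recovery harness.

In steady state the active fractions obey, per cycle (X ∈ {Rac1, RhoA}),

    d[X-GTP]/dt = V_GEF·[X-GDP]/(K1+[X-GDP]) − V_GAP·[X-GTP]/(K2+[X-GTP]),

with V_GEF and V_GAP themselves controlled by the opposing GTPase through
the PAK→GEF-H1 and GAP arms — the coupling that creates saddle-node
bifurcations and a bistable window with distinct up-switch (T1) and
down-switch (T2) thresholds.

## Worked example

```python
import numpy as np
import racrho as rr

net = rr.build_network()                      # calibrated defaults, u = 0

# hysteresis of active RhoA against the PAK-inhibitor level
h = rr.hysteresis(net, "u", np.linspace(0, 5000, 41))
print(h.bistable, h.t1, h.t2)
# True 3687.5 437.5

# inside the window the network has two stable states and a saddle
for s in rr.find_steady_states(net.with_u(2000.0), n_starts=50, seed=1):
    print(f"{s.label:9s} Rac1-GTP={s.state[1]:6.1f}  RhoA-GTP={s.state[3]:6.1f}")
# stable    Rac1-GTP=  36.2  RhoA-GTP= 504.8
# unstable  Rac1-GTP= 210.5  RhoA-GTP= 100.6
# stable    Rac1-GTP= 509.4  RhoA-GTP=  16.8
```

The forward dose sweep keeps RhoA-GTP low until the inhibitor exceeds
T1 ≈ 3690 nM, where it switches up; sweeping back down, RhoA-GTP stays
high until T2 ≈ 440 nM — a 3.25 µM-wide hysteresis loop. Rac1-GTP mirrors
the switch in the opposite direction, and at every bistable dose the
high-RhoA state carries the lower Rac1 activity.

The same memory appears in the experimental-protocol simulation: cells
pretreated for 20 min with a saturating dose and then washed out to a
test dose hold the high-RhoA state at doses where naively treated cells
stay low (`rr.dose_response_hysteresis`), and a 500-cell synthetic
population at a window dose splits into a bimodal RhoA-GTP distribution
(`analysis/06_population_bimodality.py`).

## Analysis pipeline

Numbered drivers under `analysis/` reproduce each stage and write tidy
CSVs to `results/`:

| script | what it does |
|---|---|
| `01_calibrate_defaults.py` | re-checks the shipped kinetics against the calibrator |
| `02_hysteresis_sweeps.py` | inhibitor and Rac1-total sweeps with T1/T2 |
| `03_region_map.py` | 20×20 Rac1×RhoA stability region map |
| `04_abundance_scan.py` | 5D abundance scan, association contrasts, parallel coordinates |
| `05_inhibitor_protocol.py` | naive vs pretreat/washout dose responses |
| `06_population_bimodality.py` | single-cell readout distributions per dose |
| `07_parameter_recovery.py` | fits kinetic constants to synthetic densitometry |

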