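# Methods

## The model

The package implements a deterministic mass-action / Michaelis–Menten
kinetic model of the mutual antagonism between the small GTPases Rac1 and
RhoA in a motile cell, mediated by the kinase PAK and the RhoA GEF GEF-H1:

* **Rac1 → PAK.** Rac1-GTP binds inactive PAK through the CRIB domain
  (reversible mass action); the complex autophosphorylates through an
  intramolecular mechanism, releasing active phospho-PAK (pPAK) and the
  Rac1-GTP molecule. A phosphatase (single Michaelis–Menten step) returns
  pPAK to the closed, inactive conformation.
* **PAK ⊣ GEF-H1 → RhoA.** pPAK phosphorylates GEF-H1 on inhibitory sites;
  phospho-GEF-H1 is captured by 14-3-3 (reversible mass action), which
  both sequesters it and protects the phospho-sites from the (fast)
  GEF-H1 phosphatase — only free phospho-GEF-H1 is dephosphorylated.
  Active (free, unphosphorylated) GEF-H1 drives RhoA nucleotide exchange;
  a basal Rho GAP activity opposes it.
* **RhoA ⊣ Rac1.** RhoA-GTP activates Rac1 GAPs (the ROCK→GAP axis lumped
  into a single activation step on an explicit, conserved GAP moiety);
  active GAP deactivates Rac1, closing the double-negative feedback loop.
* **Inhibitor.** A small-molecule PAK inhibitor binds inactive,
  unphosphorylated PAK, competing with Rac1-GTP binding. Its free
  intracellular concentration `u` is an external forcing, not a conserved
  species: small molecules equilibrate across the membrane within minutes,
  so depletion by target binding is neglected.

Fourteen species, fourteen reaction columns (the two reversible binding
steps are single net-rate columns; inhibitor binding and unbinding are
separate), six conserved moieties — Rac1, RhoA, PAK, GEF-H1, 14-3-3 and
RacGAP totals. Units are nM and minutes throughout. All zero-order
production is absent by construction, so the all-zero state is a fixed
point and the nonnegative orthant is forward-invariant.

Deliberate simplifications: no Cool-2-type positive feedback, no
PAK-independent Rac1 self-activation, no GDI cycling, no spatial or
stochastic kinetics; 14-3-3 is treated as a single binding site;
autophosphorylation releases Rac1-GTP (keeping Rac1 catalytic rather than
stoichiometrically consumed).

## Parameters

**Abundances** (defaults, nM): Rac1 600, RhoA 550, PAK 550, GEF-H1 100,
14-3-3 650, RacGAP 100. The five sampled totals lie inside the 0–1,000 nM
box used for abundance-space analysis. They were chosen so that an
untreated cell population (lognormal cell-to-cell variability, CV 0.15)
sits uniformly on the low-RhoA / high-Rac1 branch — the baseline state the
dosing protocols start from. Measured totals for a specific cell line can
be substituted through the YAML configuration.

**Kinetics.** The shipped `DEFAULT_KINETICS` is a calibrated reference
set, not a collection of measured constants. It was produced by the
random-search calibrator (`bifurcation.calibrate_bistable_defaults`
workflow: log-uniform draws in a box, first qualifying set wins) with the
qualifying criterion being the bistable regime itself: a hysteretic
inhibitor dose response at the default abundances, plus the regime's
reported structure — monostability without inhibitor, a Rac1-total
hysteresis window, and abundance-space association signs (bistability
with high RhoA/PAK/14-3-3 and low GEF-H1 totals). After calibration all
first- and second-order rate constants were multiplied by a common factor
of 6, which rescales time only (steady states, thresholds and the whole
bifurcation structure are invariant) so that branch switching completes
within the 20–40 min experimental incubations. Two properties of the set
worth knowing:

* Thresholds at the defaults: inhibitor up-switch T1 ≈ 3.69 µM-equivalent
  (3687.5 nM on the standard 0–5,000 nM grid), down-switch T2 ≈ 437.5 nM;
  Rac1-total window ≈ 57–145 nM at `u = 0`.
* Doubling or halving any one of the five sampled totals preserves a
  bistable inhibitor window; only its thresholds move.

The µM↔nM mapping of extracellular inhibitor doses is a free scale
(the model has no measured intracellular concentration); doses are stated
in model nM with a saturating `dose_max` of 6,000 nM.

## Steady states and stability

Six conservation laws reduce the system to 8 dimensions. Fixed points are
located by a multi-start protocol: the all-inactive and all-active corner
states plus Latin-hypercube starts on the moiety-feasible region; corners
and the leading quarter of the starts are relaxed by stiff integration
(LSODA) before every start is polished by bounded trust-region
least-squares on the reduced system (`‖rhs‖∞ < 1e-8 nM/min` accepted,
duplicates merged at relative L2 1e-6). Saddles between stable pairs are
additionally sought from midpoints. Non-degenerate systems have an odd
fixed-point count; an even count triggers a refinement pass with extra
integrated starts. Stability is read from the reduced Jacobian (central
differences, relative step 1e-6) with a ±1e-6 min⁻¹ marginality band;
the label is independent of which variables conservation eliminates (the
test suite checks the reduced spectrum against the full 14×14 Jacobian
after discarding the six conservation zero-modes).

`dynamics_class` maps stable-state counts to labels: 2 → bistable,
1 → monostable, anything else → other (the screening for bounded
non-quiescent trajectories exists for completeness; the calibrated network
has no oscillatory regime).

## Sweeps, thresholds, maps

One-parameter sweeps use **state carry-over continuation** — the relaxed
state at one grid point seeds the next — because that is what physically
produces hysteresis and mirrors the pretreat/washout protocol
(pseudo-arclength continuation is deliberately out of scope). Jumps are
detected as inter-point steps exceeding 5× the median step; T1/T2 are the
midpoints of the forward/backward jump intervals, optionally refined by
bisection on the stable-state count to 1e-3 relative resolution. Several
disjoint jumps in one direction raise an error (grid too coarse, or a
regime outside mono/bistable). Two-parameter region maps classify each
cell independently, so results do not depend on evaluation order.

One mechanistic subtlety: along the low-RhoA branch, free Rac1-GTP *rises*
slightly (≈ 9%) with inhibitor dose before switching down, because
inhibitor-bound PAK no longer sequesters Rac1-GTP in CRIB complexes. The
branch-monotonicity checks therefore assert monotone RhoA and a dominant
downward Rac1 switch, not strict Rac1 monotonicity.

## Abundance-space scan

Uniform sampling (Latin-hypercube behind a flag) of the five totals in a
box, default 0–1,000 nM per axis, each set classified by
`dynamics_class`. Association structure is summarized as bistable-minus-
monostable median contrasts per axis with a Mann–Whitney rank test;
"other" labels are excluded from contrasts. Parallel-coordinate tables
normalize over the *box*, not the realized sample, so rows remain
comparable across scans. The desk-scale default is n = 2,000 (the
100,000-sample analysis is supported but not required by the tests); at
n = 2,000 the bistable fraction is ≈ 20% with decisive contrast signs
(+RhoA, +PAK, +14-3-3, −GEF-H1; Rac1 may go either way since bistability
occupies an interior window of its axis).

## Dosing protocols

Intracellular inhibitor follows first-order kinetics toward the applied
extracellular dose with half-life `t_half` (default 3.5 min, the midpoint
of the measured 2–5 min washout range), so a washout leaves
`2^(−10/t_half)` after 10 min — exactly 25% at the 5-min upper half-life.
The naive arm applies a dose for 40 min from the untreated steady state;
the pretreated arm applies the saturating dose for 20 min (driving the
system onto the high-RhoA branch) and then washes out to the test dose
for 20 min. Hysteresis appears as the pretreated arm holding the
high-RhoA state at doses where the naive arm stays low; the summary
declares hysteresis when the maximal arm gap exceeds 20% of the readout's
dynamic range. At dose 0 the pretreated arm decays back toward the low
branch (the high state is not stable without inhibitor), so the arms
coincide only up to residual transient memory there; they coincide to
<1% at the saturating dose.

## Synthetic populations

Cell-to-cell variability: independent per-axis lognormal totals with
median equal to the nominal abundance and a given CV. Observation noise:
multiplicative lognormal on the readout (densitometry and
immunofluorescence intensities are positive and right-skewed). The
readout proxies are the raw active-GTPase concentrations; the mapping to
downstream markers (pMLC, F-actin) is deliberately identity-plus-noise.

Bimodality verdict: 1- vs 2-component Gaussian mixtures on log readouts;
bimodal iff BIC improves by more than 10 *and* the component means are
more than 2 pooled SDs apart. A numerical dip statistic (convex/concave
envelope scan over candidate modes) is reported as secondary evidence
only. The three-dose bimodality analysis (0 / 2,000 / 15,000 nM, 500
cells) uses CV 0.15: small enough that essentially all cells share the
nominal regime at the extreme doses, which is the condition under which
"bimodal only inside the window" can hold at all; at CV 0.3 the
within-window dose is still robustly bimodal, but a percent-level tail of
cells sits across the regime boundary even at extreme doses and the
mixture test (which detects well-separated minority modes by design)
flags them.

What the generator does *not* emulate: correlated protein abundances,
chemical (intrinsic) noise and stochastic branch switching, a third
subpopulation in downstream markers, imaging artefacts. Passing tests
therefore demonstrate the deterministic-switch logic under idealized
single-cell heterogeneity, not quantitative agreement with image-derived
distributions.

## Parameter recovery

Weighted least squares (weights = SEM of the replicate means, floor 2% of
signal) between the naive-arm dose response and a synthetic densitometry
table, optimizing up to four kinetic constants on a log scale with
multi-start trust-region refinement inside bounds. A flat-profile screen
(±20% profile cost) warns about non-identifiable requests. At 5%
observation noise the two headline constants (GEF-H1 phosphorylation
kcat, inhibitor on-rate) are recovered within ≈ 5%.

## Numerical choices

* Integration: LSODA, rtol 1e-8/atol 1e-10 for trajectory-level results,
  relaxed to 1e-6/1e-8 inside multi-start searches and per-cell protocol
  runs; solver clipping is never used, and trajectories stay above
  −1e-9 nM.
* Steady-state tolerance ‖rhs‖∞ < 1e-8 nM/min; dedup at relative L2 1e-6;
  eigenvalue margin 1e-6 min⁻¹.
* Degenerate inputs: all-zero kinetics yields a continuum of marginal
  fixed points, classified "other"; zero abundances make the zero state
  the unique (marginal) fixed point.
* Problem sizes in the shipped analyses (2,000-sample scans, 20×20 maps,
  41-point sweeps, 500-cell populations) are desk-scale choices that keep
  a full pipeline run in minutes on one core; every size is a parameter.

## SBML and configuration

Models round-trip through SBML Level 3 Version 2 (species with initial
concentrations, global parameters, full MathML kinetic laws, written and
read with lxml); the rate-law MathML is generated from an expression AST
that the test suite evaluates against the in-memory rate functions. The
clamped inhibitor is exported as a constant parameter — a document
represents one inhibitor level. YAML configuration files carry
abundances, kinetics, the inhibitor level and protocol constants.

## Known limitations

* The calibrated kinetics are one qualifying point in a wide admissible
  region; quantitative threshold values are properties of this reference
  set, not predictions.
* Carry-over continuation cannot trace unstable branches; the unstable
  state inside [T2, T1] comes from the multi-start search instead.
* The mixture-based bimodality rule is sensitive to well-separated
  minority modes (by design); with heavy-tailed heterogeneity it will
  flag small subpopulations that a histogram reader might dismiss.
* Deterministic branch assignment: cells exactly at threshold follow
  their carried-over state; stochastic switching is out of scope.
* The calibrated kinetics carry absolute concentration scales (fixed
  Michaelis and dissociation constants), so the bistable region does not
  dilate with the sampling box: enlarging the box to 0–5,000 nM keeps a
  nonempty bistable subset but shifts the association structure, because
  bistability stays anchored near the calibrated scales. A dimensionless
  reformulation would restore box-scale invariance and is not implemented.
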