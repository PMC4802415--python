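"""Random sampling of abundance space with per-set dynamics classification.

Emulates multi-dimensional dynamics mapping (DYVIPAC-style): draw total
abundances of Rac1, RhoA, PAK, GEF-H1 and 14-3-3 uniformly from a box,
classify each set as monostable/bistable/other, and summarize which axes
associate with bistability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, qmc

from .model import AbundanceVector, KineticParameters, build_network
from .steady_state import dynamics_class

__all__ = [
    "SAMPLED_AXES", "DEFAULT_BOX", "StabilityClassification",
    "scan", "association_summary", "parallel_coords_table",
]

#: The five abundance axes that are sampled (RacGAP total stays fixed).
SAMPLED_AXES = ("rac1_tot", "rhoa_tot", "pak_tot", "gefh1_tot", "s1433_tot")

#: Physiologically sensible sampling box, nM per axis.
DEFAULT_BOX: dict[str, tuple[float, float]] = {a: (0.0, 1000.0) for a in SAMPLED_AXES}


@dataclass
class StabilityClassification:
    abundances: AbundanceVector
    label: str
    sample_index: int
    seed: int


def scan(
    ranges: dict[str, tuple[float, float]] | None = None,
    n: int = 2000,
    kinetics: KineticParameters | None = None,
    seed: int = 1,
    racgap_tot: float | None = None,
    u: float = 0.0,
    latin_hypercube: bool = False,
    n_starts: int = 8,
) -> list[StabilityClassification]:
    """Classify ``n`` abundance sets sampled from ``ranges``.

    Uniform independent sampling by default; Latin-hypercube behind the
    ``latin_hypercube`` flag.  Deterministic under a fixed seed.
    """
    if ranges is None:
        ranges = DEFAULT_BOX
    if n < 0:
        raise ValueError("n must be >= 0")
    for axis, (lo, hi) in ranges.items():
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid range for {axis}: [{lo}, {hi}]")
    base = AbundanceVector() if racgap_tot is None \
        else AbundanceVector(racgap_tot=racgap_tot)
    rng = np.random.default_rng(seed)
    axes = list(ranges)
    lo = np.array([ranges[a][0] for a in axes])
    hi = np.array([ranges[a][1] for a in axes])
    if latin_hypercube:
        unit = qmc.LatinHypercube(d=len(axes), seed=rng).random(n)
    else:
        unit = rng.uniform(size=(n, len(axes)))
    samples = lo + unit * (hi - lo)

    out = []
    for i in range(n):
        ab = base.replace(**dict(zip(axes, samples[i])))
        net = build_network(ab, kinetics, u=u)
        label = dynamics_class(net, n_starts=n_starts, seed=seed)
        out.append(StabilityClassification(ab, label, i, seed))
    return out


def _frame(classifications: list[StabilityClassification]) -> pd.DataFrame:
    rows = [
        {**{a: getattr(c.abundances, a) for a in SAMPLED_AXES},
         "label": c.label, "sample_index": c.sample_index}
        for c in classifications
    ]
    return pd.DataFrame(rows)


def association_summary(
    classifications: list[StabilityClassification],
    min_class_size: int = 30,
) -> pd.DataFrame:
    """Per-axis contrast of bistable vs monostable samples.

    Returns a table with the median of each axis within each label, their
    difference (bistable minus monostable, nM), its sign and a Mann-Whitney
    rank statistic with p-value.  "Other"-labeled sets are excluded and
    counted separately by the caller if needed.
    """
    df = _frame(classifications)
    bi = df[df.label == "bistable"]
    mono = df[df.label == "monostable"]
    if len(bi) < min_class_size or len(mono) < min_class_size:
        raise ValueError(
            f"need >= {min_class_size} samples in each of bistable "
            f"({len(bi)}) and monostable ({len(mono)}); increase n"
        )
    rows = []
    for a in SAMPLED_AXES:
        med_b, med_m = bi[a].median(), mono[a].median()
        u_stat, p = mannwhitneyu(bi[a], mono[a], alternative="two-sided")
        rows.append({
            "axis": a,
            "median_bistable": med_b,
            "median_monostable": med_m,
            "contrast": med_b - med_m,
            "sign": int(np.sign(med_b - med_m)),
            "mannwhitney_u": u_stat,
            "p_value": p,
        })
    return pd.DataFrame(rows).set_index("axis")


def parallel_coords_table(
    classifications: list[StabilityClassification],
    ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Min-max normalize each sampled axis over the *box* (not the realized
    sample) to [0, 1]; row order preserved.  Raises on a degenerate axis."""
    if not classifications:
        raise ValueError("empty classification list")
    if ranges is None:
        ranges = DEFAULT_BOX
    df = _frame(classifications)
    out = df[["sample_index", "label"]].copy()
    for a in SAMPLED_AXES:
        lo, hi = ranges[a]
        if hi <= lo:
            raise ValueError(f"degenerate axis {a}: [{lo}, {hi}]")
        out[a] = (df[a] - lo) / (hi - lo)
    return out
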