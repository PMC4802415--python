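"""Hysteresis sweeps, two-parameter bistability maps, and default calibration.

One-parameter sweeps use state carry-over continuation — the relaxed state
at grid point k seeds grid point k+1 — which is what produces hysteresis and
mirrors the pretreat/washout experimental logic.  Saddle-node thresholds are
reported as T1 (up-switch on the forward sweep) and T2 (down-switch on the
backward sweep); for a bistable system T2 < T1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    AbundanceVector, KineticParameters, ReactionNetwork, SPECIES, build_network,
)
from .steady_state import dynamics_class, find_steady_states, _polish

__all__ = [
    "HysteresisResult", "RegionMap", "sweep1d", "hysteresis", "region2d",
    "calibrate_bistable_defaults",
]

#: Default readout species for sweep outputs.
READOUTS = ("rac_gtp", "rho_gtp")
_RAC = SPECIES.index("rac_gtp")
_RHO = SPECIES.index("rho_gtp")


class SweepError(RuntimeError):
    pass


@dataclass
class HysteresisResult:
    param_name: str
    grid: np.ndarray
    forward: dict[str, np.ndarray]    # readout name -> values along ascending grid
    backward: dict[str, np.ndarray]   # readout name -> values along ascending grid
    bistable: bool
    t1: float | None = None           # forward up-switch threshold
    t2: float | None = None           # backward down-switch threshold


@dataclass
class RegionMap:
    param_x: str
    param_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    labels: np.ndarray                # shape (len(grid_y), len(grid_x)), dtype object


def _set_param(network: ReactionNetwork, name: str, value: float) -> ReactionNetwork:
    if name == "u":
        return network.with_u(value)
    if name in network.abundances.names:
        return network.with_abundances(network.abundances.replace(**{name: value}))
    if name in network.kinetics.names:
        return ReactionNetwork(
            network.abundances, network.kinetics.replace(**{name: value}), network.u
        )
    raise KeyError(f"unknown parameter {name!r}")


def _relax_to_ss(network: ReactionNetwork, y0: np.ndarray,
                 t_chunk: float = 500.0, max_time: float = 2e4,
                 rtol: float = 1e-8) -> np.ndarray | None:
    y = np.asarray(y0, dtype=float)
    t = 0.0
    while t < max_time:
        sol = solve_ivp(lambda _t, yy: network.rhs_reduced(yy), (0.0, t_chunk), y,
                        method="LSODA", rtol=rtol, atol=rtol * 1e-2)
        if not sol.success:
            return None
        y_new = sol.y[:, -1]
        moved = np.linalg.norm(y_new - y) / max(np.linalg.norm(y), 1.0)
        y = y_new
        t += t_chunk
        if moved < 1e-10:
            break
    polished = _polish(network, y)
    return polished if polished is not None else y


def sweep1d(
    network: ReactionNetwork,
    param_name: str,
    grid: np.ndarray,
    direction: str = "forward",
    readouts: tuple[str, ...] = READOUTS,
    y0: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Carry-over continuation along ``grid`` (ascending for "forward",
    traversed descending for "backward"); returns readouts indexed by the
    ascending grid.  Non-convergent points are recorded as NaN.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    order = range(len(grid)) if direction == "forward" else range(len(grid) - 1, -1, -1)
    idx = [SPECIES.index(r) for r in readouts]
    out = {r: np.full(len(grid), np.nan) for r in readouts}

    first = grid[0] if direction == "forward" else grid[-1]
    net = _set_param(network, param_name, first)
    if y0 is None:
        # start from the branch the relaxed inactive state selects
        y = _relax_to_ss(net, net.reduced_state(net.inactive_state()))
    else:
        y = np.asarray(y0, dtype=float)
    for k in order:
        net = _set_param(network, param_name, grid[k])
        y_new = _relax_to_ss(net, y) if y is not None else None
        if y_new is None:
            continue
        y = y_new
        x = net.full_state(y)
        for r, j in zip(readouts, idx):
            out[r][k] = x[j]
    return out


def _detect_jump(values: np.ndarray, grid: np.ndarray, direction: str):
    """Locate a single switch as a step exceeding 5x the median |inter-point step|.

    Returns the parameter midpoint of the jump interval, or None; raises
    SweepError when several disjoint jump intervals are present.
    """
    steps = np.abs(np.diff(values))
    finite = steps[np.isfinite(steps)]
    if finite.size == 0:
        return None
    med = np.median(finite)
    if med == 0:
        big = np.flatnonzero(steps > 0)
    else:
        big = np.flatnonzero(steps > 5 * med)
    if big.size == 0:
        return None
    if np.any(np.diff(big) > 1):
        raise SweepError(
            "multiple jumps detected in one sweep direction; refine the grid "
            "or expect a regime other than mono/bistable"
        )
    j = big[np.argmax(steps[big])]
    return 0.5 * (grid[j] + grid[j + 1])


def hysteresis(
    network: ReactionNetwork,
    param_name: str,
    grid: np.ndarray,
    readouts: tuple[str, ...] = READOUTS,
    jump_readout: str = "rho_gtp",
) -> HysteresisResult:
    """Forward+backward sweeps with threshold extraction.

    T1 is the midpoint of the forward-sweep interval containing the jump, T2
    its backward analogue; the system is flagged bistable when both sweeps
    jump and at distinct locations.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 20:
        raise ValueError("hysteresis needs a grid with >= 20 points")
    fwd = sweep1d(network, param_name, grid, "forward", readouts)
    bwd = sweep1d(network, param_name, grid, "backward", readouts)
    t1 = _detect_jump(fwd[jump_readout], grid, "forward")
    t2 = _detect_jump(bwd[jump_readout], grid, "backward")
    bistable = t1 is not None and t2 is not None and not np.isclose(t1, t2)
    if not bistable:
        t1 = t2 = None
    return HysteresisResult(param_name, grid, fwd, bwd, bistable, t1, t2)


def refine_threshold(
    network: ReactionNetwork,
    param_name: str,
    lo: float,
    hi: float,
    rel_tol: float = 1e-3,
    n_starts: int = 16,
    seed: int = 1,
) -> float:
    """Bisect on the stable-state count to localize a saddle-node between
    ``lo`` (one count) and ``hi`` (a different count)."""
    def n_stable(v):
        net = _set_param(network, param_name, v)
        return sum(1 for s in find_steady_states(net, n_starts, seed) if s.label == "stable")
    n_lo = n_stable(lo)
    scale = max(abs(lo), abs(hi), 1e-12)
    while (hi - lo) > rel_tol * scale:
        mid = 0.5 * (lo + hi)
        if n_stable(mid) == n_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def region2d(
    network: ReactionNetwork,
    param_x: str,
    param_y: str,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    n_starts: int = 16,
    seed: int = 1,
) -> RegionMap:
    """Per-cell dynamics classification on the 2D grid.

    Cells are evaluated independently, so the result does not depend on
    evaluation order.
    """
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    for g in (grid_x, grid_y):
        if len(g) > 1 and np.any(np.diff(g) <= 0):
            raise ValueError("grids must be strictly increasing")
    labels = np.empty((len(grid_y), len(grid_x)), dtype=object)
    for i, yv in enumerate(grid_y):
        for j, xv in enumerate(grid_x):
            net = _set_param(_set_param(network, param_x, xv), param_y, yv)
            labels[i, j] = dynamics_class(net, n_starts=n_starts, seed=seed)
    return RegionMap(param_x, param_y, grid_x, grid_y, labels)


#: Search box for default-kinetics calibration: per-parameter [lo, hi]
#: multipliers applied to the box midpoint on a log scale.
DEFAULT_KINETICS_BOX: dict[str, tuple[float, float]] = {
    name: (0.5, 2.0) for name in KineticParameters().names
}


def calibrate_bistable_defaults(
    kinetics_box: dict[str, tuple[float, float]],
    abundances: AbundanceVector,
    u_grid: np.ndarray,
    seed: int = 1,
    max_iter: int = 200,
    center: KineticParameters | None = None,
) -> KineticParameters:
    """Random log-uniform search for kinetics giving inhibitor hysteresis.

    ``kinetics_box`` maps parameter names to multiplicative [lo, hi] ranges
    about ``center`` (midpoint candidate tried first).  Returns the first
    sampled set whose inhibitor dose response is hysteretic at the given
    abundances; deterministic under a fixed seed.
    """
    if center is None:
        center = KineticParameters()
    rng = np.random.default_rng(seed)
    u_grid = np.asarray(u_grid, dtype=float)

    def qualifies(kin: KineticParameters) -> bool:
        net = build_network(abundances, kin, u=0.0)
        try:
            return hysteresis(net, "u", u_grid).bistable
        except SweepError:
            return False

    if qualifies(center):
        return center
    names = list(kinetics_box)
    for _ in range(max_iter - 1):
        draws = {
            n: getattr(center, n)
            * np.exp(rng.uniform(np.log(kinetics_box[n][0]), np.log(kinetics_box[n][1])))
            for n in names
        }
        kin = center.replace(**draws)
        if qualifies(kin):
            return kin
    raise RuntimeError(
        f"no bistable kinetics found in {max_iter} draws; widen the box"
    )
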