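"""Steady-state location, stability classification, and dynamics class.

The network's six conservation laws reduce the 14-species ODE to an
8-dimensional system; fixed points are found by a multi-start protocol
(Latin-hypercube starts on the moiety-feasible region plus the all-inactive
and all-active corner states), each start integrated toward quiescence and
polished by bounded root-finding on the reduced system.  Stability comes
from the eigenvalues of the reduced Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint, solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import FREE_SPECIES, N_SPECIES, ReactionNetwork

__all__ = [
    "SteadyState",
    "simulate",
    "find_steady_states",
    "classify_stability",
    "dynamics_class",
    "RHS_TOL",
    "EIG_MARGIN",
]

#: Steady-state tolerance on the sup-norm of the right-hand side (nM/min).
RHS_TOL = 1e-8
#: Eigenvalue margin separating stable/unstable from marginal (1/min).
EIG_MARGIN = 1e-6
#: Relative L2 distance below which two fixed points are the same.
DEDUP_TOL = 1e-6


class IntegrationError(RuntimeError):
    pass


@dataclass
class SteadyState:
    """A fixed point with its stability label.

    ``label`` is "stable", "unstable" or "marginal" according to the sign of
    ``leading_eig`` (real part of the rightmost reduced-Jacobian eigenvalue)
    against the ±EIG_MARGIN band.
    """

    state: np.ndarray
    residual_norm: float
    label: str
    leading_eig: float


def simulate(
    network: ReactionNetwork,
    state0: np.ndarray,
    t_end: float,
    tol: float = 1e-8,
    t_eval: np.ndarray | None = None,
    u_of_t=None,
):
    """Integrate the full 14-species ODE with a stiff-capable solver.

    Parameters
    ----------
    u_of_t : callable, optional
        Time-varying clamped free-inhibitor concentration; overrides the
        network's fixed ``u``.

    Returns ``(times, states)`` with states of shape (len(times), 14).
    """
    state0 = np.asarray(state0, dtype=float)
    if state0.shape != (N_SPECIES,):
        raise ValueError(f"state0 must have {N_SPECIES} entries")
    if u_of_t is None:
        def f(t, x):
            return network._rhs_unchecked(x)
    else:
        def f(t, x):
            return network._rhs_unchecked(x, u_of_t(t))
    sol = solve_ivp(
        f, (0.0, t_end), state0, method="LSODA",
        rtol=tol, atol=tol * 1e-2, t_eval=t_eval, dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}")
    return sol.t, sol.y.T


def _odeint_relax(network: ReactionNetwork, y0: np.ndarray, t_end: float,
                  rtol: float = 1e-6, atol: float = 1e-8) -> np.ndarray:
    """Cheap stiff relaxation of the reduced system (low-overhead path)."""
    out = odeint(
        lambda yy, _t: network.rhs_reduced(yy), np.asarray(y0, dtype=float),
        [0.0, t_end], rtol=rtol, atol=atol, mxstep=50000,
    )
    y = out[-1]
    return y if np.all(np.isfinite(y)) else np.asarray(y0, dtype=float)


def _reduced_bounds(network: ReactionNetwork):
    a = network.abundances
    ub = {
        "rac_gtp": a.rac1_tot, "rho_gtp": a.rhoa_tot,
        "pak_rac": min(a.pak_tot, a.rac1_tot), "pak_p": a.pak_tot,
        "pak_inh": a.pak_tot, "gef_p": a.gefh1_tot,
        "gef_p_1433": min(a.gefh1_tot, a.s1433_tot), "gap_a": a.racgap_tot,
    }
    return np.zeros(len(FREE_SPECIES)), np.array([ub[s] for s in FREE_SPECIES])


def _polish(network: ReactionNetwork, y0: np.ndarray):
    """Bounded root-polish on the reduced system; returns y or None."""
    lo, hi = _reduced_bounds(network)
    y0 = np.clip(y0, lo, hi)
    res = least_squares(
        network.rhs_reduced, y0, bounds=(lo, hi),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, method="trf",
    )
    y = res.x
    if np.max(np.abs(network.rhs_reduced(y))) > RHS_TOL:
        return None
    # eliminated species must also be nonnegative
    if np.min(network.full_state(y)) < -1e-9:
        return None
    return y


def _feasible_starts(network: ReactionNetwork, n: int, seed: int) -> np.ndarray:
    """Latin-hypercube starts on (a superset of) the moiety-feasible region."""
    a = network.abundances
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=10, seed=rng)
    uhats = sampler.random(n)
    starts = np.empty((n, len(FREE_SPECIES)))
    for i, uh in enumerate(uhats):
        # PAK moiety split among (free, complexed, phospho, inhibited)
        w = -np.log(np.maximum(uh[0:4], 1e-12))
        pak = a.pak_tot * w[1:4] / np.sum(w)          # pak_rac, pak_p, pak_inh
        pak[0] = min(pak[0], a.rac1_tot)
        rac_gtp = uh[4] * max(a.rac1_tot - pak[0], 0.0)
        rho_gtp = uh[5] * a.rhoa_tot
        w2 = -np.log(np.maximum(uh[6:9], 1e-12))
        gef = a.gefh1_tot * w2[1:3] / np.sum(w2)      # gef_p, gef_p_1433
        gef[1] = min(gef[1], a.s1433_tot)
        gap_a = uh[9] * a.racgap_tot
        starts[i] = [rac_gtp, rho_gtp, pak[0], pak[1], pak[2],
                     gef[0], gef[1], gap_a]
    return starts


def _dedup(states: list[np.ndarray], scale: float) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for s in states:
        if all(np.linalg.norm(s - o) > DEDUP_TOL * max(scale, 1.0) for o in out):
            out.append(s)
    return out


def reduced_jacobian(network: ReactionNetwork, y: np.ndarray) -> np.ndarray:
    """Central finite-difference Jacobian of the reduced system (rel step 1e-6)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    jac = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(abs(y[j]), 1.0)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        jac[:, j] = (network.rhs_reduced(yp) - network.rhs_reduced(ym)) / (2 * h)
    return jac


def classify_stability(network: ReactionNetwork, state: np.ndarray) -> tuple[str, float]:
    """Label a steady state via the reduced-Jacobian spectrum.

    Requires ``state`` to satisfy the steady-state tolerance; returns
    (label, leading eigenvalue real part).
    """
    state = np.asarray(state, dtype=float)
    r = network._rhs_unchecked(state)
    if np.max(np.abs(r)) > 10 * RHS_TOL:
        raise ValueError(
            f"state is not steady: sup-norm rhs {np.max(np.abs(r)):.3g} nM/min"
        )
    y = network.reduced_state(state)
    lead = float(np.max(np.linalg.eigvals(reduced_jacobian(network, y)).real))
    if lead < -EIG_MARGIN:
        label = "stable"
    elif lead > EIG_MARGIN:
        label = "unstable"
    else:
        label = "marginal"
    return label, lead


def find_steady_states(
    network: ReactionNetwork,
    n_starts: int = 50,
    seed: int = 1,
    relax_time: float = 500.0,
) -> list[SteadyState]:
    """Multi-start search for all fixed points of the network.

    Protocol: Latin-hypercube starts on the moiety-feasible region plus the
    all-inactive / all-active corner states; each start is relaxed by a short
    stiff integration then polished by bounded root-finding on the reduced
    system; duplicates merged at relative L2 < 1e-6.  Unstable saddle states
    are additionally sought by root-finding from midpoints between distinct
    stable states.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    scale = float(np.max(network.abundances.as_array()))
    if scale == 0.0:
        zero = np.zeros(N_SPECIES)
        return [SteadyState(zero, 0.0, "marginal", 0.0)]

    corner_starts = [
        network.reduced_state(network.inactive_state()),
        network.reduced_state(network.active_state()),
    ]
    lhs_starts = list(_feasible_starts(network, max(n_starts - 2, 0), seed))
    all_starts = (corner_starts + lhs_starts)[:n_starts] if n_starts < 2 \
        else corner_starts + lhs_starts
    # corners and the leading hypercube starts relax by integration to land
    # in a basin; the rest are root-polished directly
    n_integrated = max(2, min(len(all_starts), 2 + n_starts // 4))

    roots: list[np.ndarray] = []

    def _add_roots(starts, integrate_all=False):
        for i, y0 in enumerate(starts):
            if integrate_all or i < n_integrated:
                t_relax = 1500.0 if (not integrate_all and i < 2) else relax_time
                y_end = _odeint_relax(network, y0, t_relax)
            else:
                y_end = y0
            y = _polish(network, y_end)
            if y is not None and all(
                np.linalg.norm(y - r) > DEDUP_TOL * max(scale, 1.0) for r in roots
            ):
                roots.append(y)

    def _saddle_hunt(labeled):
        stables = [y for y, lab, _ in labeled if lab == "stable"]
        for i in range(len(stables)):
            for j in range(i + 1, len(stables)):
                mid = 0.5 * (stables[i] + stables[j])
                y = _polish(network, mid)
                if y is not None and all(
                    np.linalg.norm(y - r) > DEDUP_TOL * max(scale, 1.0)
                    for r in roots
                ):
                    roots.append(y)
                    st = network.full_state(y)
                    labeled.append((y, *classify_stability(network, st)))

    def _label_all():
        labeled = []
        for y in roots:
            st = network.full_state(y)
            labeled.append((y, *classify_stability(network, st)))
        return labeled

    _add_roots(all_starts)
    labeled = _label_all()
    _saddle_hunt(labeled)

    # non-degenerate systems have an odd fixed-point count; an even count
    # means a root was missed, so refine with extra integrated starts
    if roots and len(roots) % 2 == 0:
        extra = _feasible_starts(network, 12, seed + 1)
        _add_roots(extra, integrate_all=True)
        labeled = _label_all()
        _saddle_hunt(labeled)

    if not roots:
        warnings.warn("no start converged to a steady state", RuntimeWarning)
        return []

    out = []
    for y, lab, eig in labeled:
        st = network.full_state(y)
        out.append(SteadyState(
            state=st,
            residual_norm=float(np.max(np.abs(network._rhs_unchecked(st)))),
            label=lab,
            leading_eig=eig,
        ))
    # deterministic ordering: by Rac1-GTP then RhoA-GTP
    out.sort(key=lambda s: (s.state[1], s.state[3]))
    return out


def dynamics_class(
    network: ReactionNetwork,
    n_starts: int = 50,
    seed: int = 1,
) -> str:
    """Classify a network as monostable, bistable or other.

    Bistable iff exactly two stable fixed points are found, monostable iff
    exactly one; zero or more than two stable states — including the
    bounded-but-non-quiescent trajectories that signal oscillations — map
    to "other".
    """
    states = find_steady_states(network, n_starts=n_starts, seed=seed)
    n_stable = sum(1 for s in states if s.label == "stable")
    if n_stable == 2:
        return "bistable"
    if n_stable == 1:
        return "monostable"
    return "other"
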