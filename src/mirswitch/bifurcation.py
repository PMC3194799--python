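"""Bifurcation sweeps, regime classification, and two-parameter phase maps.

The fixed-point problem reduces to a scalar cubic, so one-parameter sweeps
re-solve globally at every stimulus value instead of continuing branches --
a dense re-solve cannot lose a branch in a two-variable model.  Saddle-node
(fold) points are bisected on root-count changes, Hopf points on the sign of
the real part of a complex-conjugate eigenvalue pair along a linked branch.

Regimes follow the fixed-point census plus, where a census alone is not
conclusive, a short simulation: an excitability test pulse (does a standard
pulse elicit a large excursion that fully recovers?) and a limit-cycle
verification (do sustained periodic peaks survive the transient?).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import DimensionlessParams
from .steady_states import SteadyState, solve_steady_states
from . import dynamics
from .dynamics import _batch_rk4, _detect_cycles, _rk4_series
from .stimulus import StimulusProtocol

log = logging.getLogger(__name__)

__all__ = [
    "BifurcationPoint",
    "BranchDiagram",
    "PhaseDiagram2D",
    "sweep_alpha",
    "locate_saddle_nodes",
    "locate_hopf",
    "switch_character",
    "pointwise_regime",
    "phase_diagram",
    "hysteresis_loop",
]

BRACKET_TOL = 1e-8
#: Standard excitability test pulse: rectangular, 5 time units, this far
#: above the resting stimulus (the reference pulse protocol).
TEST_PULSE_AMPLITUDE = 0.16
TEST_PULSE_WINDOW = (20.0, 25.0)


@dataclass(frozen=True)
class BifurcationPoint:
    kind: str  # saddle_node | hopf
    alpha_at: float
    phi_at: float
    bracket_width: float


@dataclass
class BranchDiagram:
    params: DimensionlessParams
    alpha_grid: np.ndarray
    states: list[list[SteadyState]]
    saddle_nodes: list[BifurcationPoint] = field(default_factory=list)
    hopf_points: list[BifurcationPoint] = field(default_factory=list)
    switch_character: str | None = None

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.states])


@dataclass
class PhaseDiagram2D:
    x_param: str
    y_param: str
    x_grid: np.ndarray
    y_grid: np.ndarray
    fixed: DimensionlessParams
    labels: np.ndarray  # shape (len(y_grid), len(x_grid)), dtype object
    saddle_node_boundary: list[tuple[float, float]] = field(default_factory=list)
    hopf_boundary: list[tuple[float, float]] = field(default_factory=list)
    mode: str = "regime"


def _n_roots(p: DimensionlessParams, alpha: float) -> int:
    states = solve_steady_states(p, alpha=alpha)
    if any(s.fold_degenerate for s in states):
        # a degenerate pair counts once for bracketing purposes
        return len(states) - 1
    return len(states)


def _real_roots(p: DimensionlessParams, alpha: float) -> np.ndarray:
    """Sorted real roots of the fixed-point cubic, sign-unrestricted.

    Fold bracketing counts real roots rather than physical (phi >= 0) ones:
    a root crossing phi = 0 changes the physical census without any
    bifurcation, while a genuine fold changes the real-root count 3 <-> 1
    wherever it sits on the alpha axis.
    """
    from .steady_states import steady_state_polynomial

    roots = np.roots(steady_state_polynomial(p, alpha=alpha))
    scale = max(1.0, float(np.max(np.abs(roots))))
    return np.sort(np.array([r.real for r in roots if abs(r.imag) <= 1e-7 * scale]))


def _n_real(p: DimensionlessParams, alpha: float) -> int:
    return len(_real_roots(p, alpha))


def sweep_alpha(p: DimensionlessParams, alpha_grid) -> BranchDiagram:
    """Full steady-state sets along an ascending stimulus grid."""
    grid = np.asarray(alpha_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 50:
        raise ValueError("alpha_grid must be a 1-D ascending grid with >= 50 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("alpha_grid must be strictly ascending")
    states = [solve_steady_states(p, alpha=a) for a in grid]
    d = BranchDiagram(params=p, alpha_grid=grid, states=states)
    d.saddle_nodes = locate_saddle_nodes(d)
    d.hopf_points = locate_hopf(d)
    d.switch_character = switch_character(p)
    log.info(
        "sweep over alpha [%g, %g]: %d saddle-nodes, %d Hopf points, %s",
        grid[0], grid[-1], len(d.saddle_nodes), len(d.hopf_points),
        d.switch_character,
    )
    return d


def _bisect_fold(p: DimensionlessParams, lo: float, hi: float, depth: int = 0):
    """Bisect root-count changes in (lo, hi); recurses if a midpoint reveals
    an interior bistable sliver the outer bracket missed."""
    n_lo, n_hi = _n_real(p, lo), _n_real(p, hi)
    out = []
    if n_lo == n_hi:
        if depth >= 3:
            return out
        mid = 0.5 * (lo + hi)
        if _n_real(p, mid) != n_lo:
            out += _bisect_fold(p, lo, mid, depth + 1)
            out += _bisect_fold(p, mid, hi, depth + 1)
        return out
    while hi - lo > BRACKET_TOL:
        mid = 0.5 * (lo + hi)
        n_mid = _n_real(p, mid)
        if n_mid == n_lo:
            lo = mid
        elif n_mid == n_hi:
            hi = mid
        else:  # interior sliver: split and recurse on both halves
            if depth < 3:
                return (
                    _bisect_fold(p, lo, mid, depth + 1)
                    + _bisect_fold(p, mid, hi, depth + 1)
                )
            hi = mid
    alpha_at = 0.5 * (lo + hi)
    side = lo if n_lo > n_hi else hi
    phis = _real_roots(p, side)
    if len(phis) >= 2:
        gaps = np.diff(phis)
        i = int(np.argmin(gaps))
        phi_at = 0.5 * (phis[i] + phis[i + 1])
    else:
        phi_at = float(phis[0])
    if phi_at < -1e-6:
        return out  # collision of unphysical branches; not a fold of the model
    out.append(
        BifurcationPoint(
            kind="saddle_node", alpha_at=float(alpha_at), phi_at=float(phi_at),
            bracket_width=float(hi - lo),
        )
    )
    return out


def locate_saddle_nodes(d: BranchDiagram) -> list[BifurcationPoint]:
    """Fold points on the sweep grid, bisected to a 1e-8 alpha bracket."""
    out: list[BifurcationPoint] = []
    grid, counts = d.alpha_grid, d.counts()
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            out += _bisect_fold(d.params, grid[i], grid[i + 1])
    return sorted(out, key=lambda b: b.alpha_at)


def _max_re(s: SteadyState) -> float:
    return max(e.real for e in s.eigenvalues)


def _has_imag(s: SteadyState, tol: float = 1e-6) -> bool:
    return any(abs(e.imag) > tol for e in s.eigenvalues)


def locate_hopf(d: BranchDiagram) -> list[BifurcationPoint]:
    """Hopf points: eigenvalue real-part sign changes on linked branches.

    Branches are linked by phi-rank inside each maximal run of constant
    root count (ordered roots of a cubic cannot cross without a fold), and
    each sign change of the leading real part is bisected; a crossing only
    counts when the eigenvalue pair is complex (|Im| > 1e-6) there.
    """
    p = d.params
    grid = d.alpha_grid
    counts = d.counts()
    out: list[BifurcationPoint] = []
    run_start = 0
    for i in range(1, len(grid) + 1):
        if i == len(grid) or counts[i] != counts[run_start]:
            nb = counts[run_start]
            for j in range(nb):
                for k in range(run_start, i - 1):
                    s0, s1 = d.states[k][j], d.states[k + 1][j]
                    if np.sign(_max_re(s0)) != np.sign(_max_re(s1)):
                        bp = _bisect_hopf(p, grid[k], grid[k + 1], j, nb)
                        if bp is not None:
                            out.append(bp)
            run_start = i
    dedup: list[BifurcationPoint] = []
    for b in sorted(out, key=lambda b: b.alpha_at):
        if not dedup or abs(b.alpha_at - dedup[-1].alpha_at) > 1e-6:
            dedup.append(b)
    return dedup


def _bisect_hopf(
    p: DimensionlessParams, lo: float, hi: float, j: int, nb: int
) -> BifurcationPoint | None:
    def branch_state(a: float) -> SteadyState | None:
        st = solve_steady_states(p, alpha=a)
        return st[j] if len(st) == nb else None

    s_lo = branch_state(lo)
    s_hi = branch_state(hi)
    if s_lo is None or s_hi is None:
        return None
    sign_lo = np.sign(_max_re(s_lo))
    while hi - lo > BRACKET_TOL:
        mid = 0.5 * (lo + hi)
        s_mid = branch_state(mid)
        if s_mid is None:  # fold slipped inside the bracket; abandon
            return None
        if np.sign(_max_re(s_mid)) == sign_lo:
            lo, s_lo = mid, s_mid
        else:
            hi, s_hi = mid, s_mid
    if not (_has_imag(s_lo) or _has_imag(s_hi)):
        return None  # degenerate real crossing, not a Hopf point
    return BifurcationPoint(
        kind="hopf", alpha_at=float(0.5 * (lo + hi)),
        phi_at=float(0.5 * (s_lo.phi_star + s_hi.phi_star)),
        bracket_width=float(hi - lo),
    )


def _fold_scan(p: DimensionlessParams, lo: float, hi: float, n: int = 400):
    """All fold alphas in [lo, hi] from a dense count scan plus bisection."""
    grid = np.linspace(lo, hi, n)
    counts = [_n_real(p, a) for a in grid]
    folds: list[BifurcationPoint] = []
    for i in range(n - 1):
        if counts[i] != counts[i + 1]:
            folds += _bisect_fold(p, grid[i], grid[i + 1])
    return sorted(folds, key=lambda b: b.alpha_at), grid, counts


def switch_character(p: DimensionlessParams) -> str:
    """monostable | bistable_switch | one_way_switch over the physical window.

    The scan extends well below the physical stimulus window so that a
    deactivating fold at negative (unphysical) alpha is still found: that is
    precisely the signature of a one-way switch, where the on-state cannot
    be exited by any admissible stimulus.
    """
    lo, hi = p.alpha_range
    span = hi - lo
    ext_lo = lo - 2.0 * span
    folds, grid, counts = _fold_scan(p, ext_lo, hi)
    if not folds and max(counts) == 1:
        return "monostable"
    # bistable intervals: spans between consecutive edges where the count is 3
    fold_alphas = [b.alpha_at for b in folds]
    edges = [ext_lo] + fold_alphas + [hi]
    intervals = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a > BRACKET_TOL and _n_real(p, 0.5 * (a + b)) == 3:
            left = -np.inf if a == ext_lo else a  # fold below the scan floor
            right = np.inf if b == hi else b
            intervals.append((left, right))
    if not intervals:
        return "monostable"
    lo_fold, hi_fold = intervals[0][0], intervals[-1][1]
    if min(hi, hi_fold) <= max(lo, lo_fold):
        return "monostable"  # bistability exists but not inside the window
    if lo_fold >= lo:  # boundary inclusive: fold exactly at alpha_min switches
        return "bistable_switch"
    return "one_way_switch"


# ---------------------------------------------------------------------------
# pointwise regime classification (monostable/bistable/excitable/oscillatory)
# ---------------------------------------------------------------------------

def _oscillation_batch(ps: list[DimensionlessParams], t_end=2000.0, dt=0.02):
    """Verify sustained limit cycles for parameter points with no stable state.

    The relaxation period scales like the slow miRNA timescale 1/epsilon
    (about 170 time units at the reference epsilon = 0.02), so the run must
    be long enough to hold at least three post-transient cycles."""
    if not ps:
        return []
    starts = []
    for q in ps:
        st = solve_steady_states(q)
        s = st[len(st) // 2]
        # start well off the focus: near a weakly unstable spiral the linear
        # growth rate can be ~1e-3 and an infinitesimal kick would not clear
        # the transient within the run; the cycle attracts from outside
        starts.append((s.phi_star + 0.3, s.mu_star))
    phi0 = np.array([s[0] for s in starts])
    mu0 = np.array([s[1] for s in starts])
    kappa = np.array([q.kappa for q in ps])
    gamma = np.array([q.gamma for q in ps])
    beta = np.array([q.beta for q in ps])
    eps = np.array([q.epsilon for q in ps])
    alpha = np.array([q.alpha for q in ps])
    times, hist, _, _ = _batch_rk4(
        phi0, mu0, lambda t: alpha, kappa, gamma, beta, eps, t_end, dt,
        record_every=20,
    )
    half = times >= t_end / 2
    results = []
    for i in range(len(ps)):
        cyc = _detect_cycles(times[half], hist[half, i])
        ok = cyc is not None and np.std(cyc["periods"]) < 0.05 * np.mean(cyc["periods"])
        results.append(bool(ok))
    return results


def _excitable_batch(
    ps: list[DimensionlessParams],
    rests: list[SteadyState],
    mids: list[float],
    t_end=300.0,
    dt=0.01,
    recovery_tol=1e-3,
):
    """Pulse test: excursion above the middle branch, then full recovery."""
    if not ps:
        return []
    phi0 = np.array([r.phi_star for r in rests])
    mu0 = np.array([r.mu_star for r in rests])
    kappa = np.array([q.kappa for q in ps])
    gamma = np.array([q.gamma for q in ps])
    beta = np.array([q.beta for q in ps])
    eps = np.array([q.epsilon for q in ps])
    base = np.array([q.alpha for q in ps])
    t_on, t_off = TEST_PULSE_WINDOW

    def alpha_of_t(t):
        return base + (TEST_PULSE_AMPLITUDE if t_on <= t < t_off else 0.0)

    times, hist, phi_end, _ = _batch_rk4(
        phi0, mu0, alpha_of_t, kappa, gamma, beta, eps, t_end, dt, record_every=10
    )
    peak = hist.max(axis=0)
    results = []
    for i in range(len(ps)):
        excursion = peak[i] > mids[i]
        recovered = abs(phi_end[i] - phi0[i]) < recovery_tol
        results.append(bool(excursion and recovered))
    return results


def pointwise_regime(p: DimensionlessParams) -> str:
    """Dynamical regime at a single parameter point (alpha = the stimulus)."""
    labels = _regime_batch([p])
    return labels[0]


def _regime_batch(ps: list[DimensionlessParams]) -> list[str]:
    """Regime labels for many parameter points, batching the simulations."""
    labels: list[str | None] = [None] * len(ps)
    osc_idx: list[int] = []
    exc_idx: list[int] = []
    exc_rest: list[SteadyState] = []
    exc_mid: list[float] = []
    for i, q in enumerate(ps):
        states = solve_steady_states(q)
        stable = [s for s in states if s.stable]
        if len(stable) >= 2:
            labels[i] = "bistable"
        elif len(stable) == 0:
            osc_idx.append(i)
        elif len(states) == 3 and len(stable) == 1:
            exc_idx.append(i)
            exc_rest.append(stable[0])
            exc_mid.append(states[1].phi_star)
        else:
            labels[i] = "monostable"
    osc_ok = _oscillation_batch([ps[i] for i in osc_idx])
    for i, ok in zip(osc_idx, osc_ok):
        labels[i] = "oscillatory" if ok else "unclassified"
    exc_ok = _excitable_batch([ps[i] for i in exc_idx], exc_rest, exc_mid)
    for i, ok in zip(exc_idx, exc_ok):
        labels[i] = "excitable" if ok else "monostable"
    return labels  # type: ignore[return-value]


def _with_param(p: DimensionlessParams, name: str, value: float) -> DimensionlessParams:
    if name == "alpha":
        return p.with_alpha(float(value))
    return replace(p, **{name: float(value)})


def phase_diagram(
    x_param: str,
    y_param: str,
    x_grid,
    y_grid,
    fixed: DimensionlessParams,
    mode: str = "regime",
) -> PhaseDiagram2D:
    """Two-parameter regime (or switch-character) map with boundary curves.

    ``mode='regime'`` labels each cell monostable/bistable/excitable/
    oscillatory via :func:`pointwise_regime`; ``mode='switch'`` labels cells
    monostable/bistable_switch/one_way_switch via :func:`switch_character`.
    Saddle-node and Hopf boundary points are bisected per column between
    cells with differing labels.
    """
    xg = np.asarray(x_grid, float)
    yg = np.asarray(y_grid, float)
    if mode == "regime" and (len(xg) < 40 or len(yg) < 40):
        warnings.warn("phase_diagram grids below 40x40 may miss thin regimes")
    points = [
        _with_param(_with_param(fixed, x_param, x), y_param, y)
        for y in yg
        for x in xg
    ]
    if mode == "regime":
        flat = _regime_batch(points)
    elif mode == "switch":
        flat = [switch_character(q) for q in points]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.array(flat, dtype=object).reshape(len(yg), len(xg))

    sn_pts: list[tuple[float, float]] = []
    hopf_pts: list[tuple[float, float]] = []
    for ix, x in enumerate(xg):
        col = _with_param(fixed, x_param, x)
        for iy in range(len(yg) - 1):
            if labels[iy, ix] == labels[iy + 1, ix]:
                continue
            kind, y_at = _bisect_structure(col, y_param, yg[iy], yg[iy + 1])
            if kind == "saddle_node":
                sn_pts.append((float(x), y_at))
            elif kind == "hopf":
                hopf_pts.append((float(x), y_at))
    d = PhaseDiagram2D(
        x_param=x_param, y_param=y_param, x_grid=xg, y_grid=yg, fixed=fixed,
        labels=labels, saddle_node_boundary=sn_pts, hopf_boundary=hopf_pts,
        mode=mode,
    )
    tally = {lab: int(np.sum(labels == lab)) for lab in np.unique(labels)}
    log.info("phase diagram %s x %s: %s", x_param, y_param, tally)
    return d


def _structure(p: DimensionlessParams):
    states = solve_steady_states(p)
    n = len(states) - (1 if any(s.fold_degenerate for s in states) else 0)
    n_stable = sum(s.stable for s in states)
    return n, n_stable


def _bisect_structure(p: DimensionlessParams, name: str, lo: float, hi: float):
    """Classify and locate the structural change between two grid cells."""
    (n_lo, s_lo) = _structure(_with_param(p, name, lo))
    (n_hi, s_hi) = _structure(_with_param(p, name, hi))
    if n_lo == n_hi and s_lo == s_hi:
        return "label_only", 0.5 * (lo + hi)
    kind = "saddle_node" if n_lo != n_hi else "hopf"
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        n_m, s_m = _structure(_with_param(p, name, mid))
        if (n_m, s_m) == (n_lo, s_lo):
            lo = mid
        else:
            hi = mid
        if hi - lo <= BRACKET_TOL:
            break
    return kind, float(0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# hysteresis
# ---------------------------------------------------------------------------

def hysteresis_loop(
    p: DimensionlessParams,
    alpha_lo: float | None = None,
    alpha_hi: float | None = None,
    ramp_rate: float = 2e-5,
    dt: float = 0.02,
    slope_threshold: float = 100.0,
) -> dict:
    """Quasi-static triangular stimulus ramp; returns jump locations.

    The stimulus rises linearly from ``alpha_lo`` to ``alpha_hi`` and back
    at ``ramp_rate`` per time unit (slow against both the protein timescale
    1 and the miRNA timescale 1/epsilon).  A jump is scored where |dphi/
    dalpha| first exceeds ``slope_threshold`` -- quasi-static branch slopes
    are O(10), fold transitions are orders of magnitude steeper.
    """
    lo = p.alpha_range[0] if alpha_lo is None else alpha_lo
    hi = p.alpha_range[1] if alpha_hi is None else alpha_hi
    span = hi - lo
    n_leg = int(round(span / ramp_rate / dt))

    start = dynamics.rest_state(p, alpha=lo)
    phi, mu = start.phi_star, start.mu_star

    def run_leg(phi0, mu0, a_from, a_to):
        a_steps = np.linspace(a_from, a_to, n_leg + 1)
        a0 = a_steps[:-1]
        a1 = a_steps[1:]
        am = 0.5 * (a0 + a1)
        ts, phis, mus, alphas, _ = _rk4_series(
            phi0, mu0, p, a0, am, a1, dt, store_every=max(1, n_leg // 4000)
        )
        return alphas, phis, mus

    a_up, phi_up, mu_up = run_leg(phi, mu, lo, hi)
    a_dn, phi_dn, mu_dn = run_leg(phi_up[-1], mu_up[-1], hi, lo)

    def jump(alphas, phis, direction):
        dphi = np.diff(phis) * direction
        dalpha = np.abs(np.diff(alphas))
        dalpha[dalpha == 0] = np.inf
        slopes = dphi / dalpha
        idx = np.where(slopes > slope_threshold)[0]
        if len(idx) == 0:
            return None
        return float(alphas[idx[0]])

    jump_up = jump(a_up, phi_up, +1.0)
    jump_down = jump(a_dn, phi_dn, -1.0)
    max_gap = float(
        np.max(np.abs(np.interp(a_up, a_dn[::-1], phi_dn[::-1]) - phi_up))
    )
    return {
        "up": {"alpha": a_up, "phi": phi_up, "mu": mu_up},
        "down": {"alpha": a_dn, "phi": phi_dn, "mu": mu_dn},
        "jump_up_alpha": jump_up,
        "jump_down_alpha": jump_down,
        "max_gap": max_gap,
        "ramp_rate": ramp_rate,
    }
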