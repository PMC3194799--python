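"""Deterministic time integration and signal-response classification.

The integrator is the classical fixed-step fourth-order Runge-Kutta scheme;
the stimulus protocol is evaluated at the stage times (right-continuous at
discontinuities).  Transient negative concentrations -- which can only arise
under noisy stimuli -- are clamped to zero before each right-hand-side
evaluation and the clamp events are counted in the trajectory metadata, so
the physical non-negativity approximation stays auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .model_core import DimensionlessParams
from .steady_states import solve_steady_states
from .stimulus import StimulusProtocol

__all__ = [
    "Trajectory",
    "integrate_rk4",
    "classify_response",
    "oscillation_metrics",
    "phase_portrait",
    "response_stats",
]


@dataclass
class Trajectory:
    """Uniformly sampled time course with integrator provenance."""

    t: np.ndarray
    phi: np.ndarray
    mu: np.ndarray
    alpha: np.ndarray  # effective stimulus at each stored sample
    protocol: StimulusProtocol
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.meta.get("dt", self.t[1] - self.t[0]))

    def window(self, t0: float, t1: float) -> np.ndarray:
        mask = (self.t >= t0) & (self.t <= t1)
        return mask


def _integrate_scalar(
    phi0: float,
    mu0: float,
    p: DimensionlessParams,
    protocol: StimulusProtocol,
    t_end: float,
    dt: float,
    rng: np.random.Generator | None = None,
    store_every: int = 1,
    scheme: str = "rk4",
) -> Trajectory:
    """Shared fixed-step RK4 core for one cell; optional frozen-step noise.

    When ``rng`` is given and the protocol carries ``noise_variance > 0``,
    a Gaussian stimulus offset of standard deviation sigma/sqrt(dt) is drawn
    once per step and held fixed across the four stages (additive noise
    through alpha only).  With sigma = 0 the noisy path is bitwise identical
    to the deterministic one.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be > 0")
    n = int(round(t_end / dt))
    tgrid = dt * np.arange(n)
    # stage stimulus values, precomputed vectorized (piecewise-constant)
    a0 = np.asarray(protocol.evaluate(tgrid), float) + np.zeros(n)
    am = np.asarray(protocol.evaluate(tgrid + 0.5 * dt), float) + np.zeros(n)
    a1 = np.asarray(protocol.evaluate(tgrid + dt), float) + np.zeros(n)

    sigma = math.sqrt(protocol.noise_variance)
    if sigma > 0 and rng is not None:
        xi = (sigma / math.sqrt(dt)) * rng.standard_normal(n)
        a0, am, a1 = a0 + xi, am + xi, a1 + xi  # noise frozen across stages
    ts, phis, mus, alphas, clamps = _rk4_series(
        float(phi0), float(mu0), p, a0, am, a1, dt, store_every
    )
    meta = {
        "scheme": scheme,
        "dt": dt,
        "store_every": store_every,
        "clamp_count": clamps,
        "sigma2": protocol.noise_variance,
    }
    return Trajectory(
        t=ts, phi=phis, mu=mus, alpha=alphas, protocol=protocol, meta=meta
    )


def _rk4_series(
    phi0: float,
    mu0: float,
    p: DimensionlessParams,
    a0: np.ndarray,
    am: np.ndarray,
    a1: np.ndarray,
    dt: float,
    store_every: int = 1,
):
    """Fixed-step RK4 over precomputed per-step stage stimulus series."""
    n = len(a0)
    kappa, gamma, beta, eps = p.kappa, p.gamma, p.beta, p.epsilon

    def f(phi: float, mu: float, a: float) -> tuple[float, float]:
        if phi < 0.0:
            phi = 0.0
        if mu < 0.0:
            mu = 0.0
        d = 1.0 + phi * phi + gamma * mu
        return a + kappa * phi * phi / d - phi, eps * (beta + phi - mu)

    n_store = n // store_every + 2
    ts = np.empty(n_store)
    phis = np.empty(n_store)
    mus = np.empty(n_store)
    alphas = np.empty(n_store)
    av0, avm, av1 = a0.tolist(), am.tolist(), a1.tolist()
    phi, mu = float(phi0), float(mu0)
    clamps = 0
    j = 0
    for k in range(n):
        if k % store_every == 0:
            ts[j], phis[j], mus[j], alphas[j] = k * dt, phi, mu, av0[k]
            j += 1
        if phi < 0.0 or mu < 0.0:
            clamps += 1
            phi = max(phi, 0.0)
            mu = max(mu, 0.0)
        s0, sm, s1 = av0[k], avm[k], av1[k]
        k1p, k1m = f(phi, mu, s0)
        k2p, k2m = f(phi + 0.5 * dt * k1p, mu + 0.5 * dt * k1m, sm)
        k3p, k3m = f(phi + 0.5 * dt * k2p, mu + 0.5 * dt * k2m, sm)
        k4p, k4m = f(phi + dt * k3p, mu + dt * k3m, s1)
        phi += dt / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
        mu += dt / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        if not (math.isfinite(phi) and math.isfinite(mu)):
            raise RuntimeError(
                f"integration diverged at step {k} (t={k * dt:.4f}): "
                f"phi={phi!r}, mu={mu!r}"
            )
    ts[j], phis[j], mus[j], alphas[j] = n * dt, phi, mu, av1[-1]
    return ts[: j + 1], phis[: j + 1], mus[: j + 1], alphas[: j + 1], clamps


def integrate_rk4(
    initial,
    p: DimensionlessParams,
    protocol: StimulusProtocol,
    t_end: float,
    dt: float = 0.01,
    store_every: int = 1,
) -> Trajectory:
    """Deterministic RK4 integration of the dimensionless model."""
    phi0, mu0 = (initial.phi, initial.mu) if hasattr(initial, "phi") else initial
    return _integrate_scalar(
        phi0, mu0, p, protocol, t_end, dt, rng=None, store_every=store_every,
        scheme="rk4",
    )


def rest_state(p: DimensionlessParams, alpha: float | None = None):
    """Off-state fixed point (lowest stable phi) at the given stimulus level.

    This is the default initial condition for signal-response runs: the
    system rests at the basal stimulus before the protocol perturbs it.
    """
    states = solve_steady_states(p if alpha is None else p.with_alpha(alpha))
    stable = [s for s in states if s.stable]
    if not stable:
        raise ValueError(
            f"no stable fixed point at alpha={alpha if alpha is not None else p.alpha}"
        )
    return stable[0]


def _detect_cycles(t: np.ndarray, phi: np.ndarray, min_amp: float = 1e-3):
    """Peak/trough bookkeeping shared by the oscillation checks."""
    span = float(phi.max() - phi.min())
    if span < min_amp:
        return None
    prom = 0.25 * span
    peaks, _ = find_peaks(phi, prominence=prom)
    troughs, _ = find_peaks(-phi, prominence=prom)
    if len(peaks) < 3 or len(troughs) < 2:
        return None
    periods = np.diff(t[peaks])
    return {"peaks": peaks, "troughs": troughs, "periods": periods, "span": span}


def classify_response(
    traj: Trajectory,
    p: DimensionlessParams,
    settle_tol: float = 1e-5,
    return_tol: float = 1e-3,
) -> str:
    """Label a signal-response run.

    ``irreversible_switch``: ends on the on-branch after the stimulus is back
    at (or the system is left at) a level where it started on the off-branch.
    ``excitable_pulse``: one large excursion above the middle-branch phi then
    a return to the initial rest state.  ``sustained_oscillation``: periodic
    peaks persisting to the end of the run.  ``no_switch`` otherwise;
    ``unclassified`` if the trajectory has not settled.
    """
    t, phi = traj.t, traj.phi
    half = t >= t[-1] / 2
    cyc = _detect_cycles(t[half], phi[half])
    if cyc is not None and np.std(cyc["periods"]) < 0.05 * np.mean(cyc["periods"]):
        return "sustained_oscillation"

    final_alpha = float(traj.protocol.evaluate(t[-1]))
    from .model_core import rhs_dimensionless

    dphi, dmu = rhs_dimensionless((phi[-1], traj.mu[-1]), p, alpha_override=final_alpha)
    if max(abs(float(dphi)), abs(float(dmu))) > settle_tol:
        return "unclassified"

    base_states = solve_steady_states(p.with_alpha(traj.protocol.base_level))
    final_states = solve_steady_states(p.with_alpha(final_alpha))
    phi0 = phi[0]
    if len(base_states) == 3:
        phi_mid = base_states[1].phi_star
    else:
        phi_mid = 0.5 * (base_states[0].phi_star + base_states[-1].phi_star)
    stable_final = [s for s in final_states if s.stable]
    on_phi = max((s.phi_star for s in stable_final), default=None)

    excursion = float(phi.max()) > phi_mid
    if abs(phi[-1] - phi0) < return_tol:
        return "excitable_pulse" if excursion else "no_switch"
    if on_phi is not None and abs(phi[-1] - on_phi) < return_tol and phi[-1] > phi_mid:
        return "irreversible_switch"
    return "no_switch"


def oscillation_metrics(traj: Trajectory, n_cycles: int = 5) -> dict:
    """Period, amplitude and rise/fall asymmetry of a sustained oscillation.

    Computed on the last ``n_cycles`` detected cycles after discarding the
    first half of the run.  The relaxation character of the limit cycle
    shows up as a rise/fall ratio above one: the protein climbs slowly along
    the slow miRNA drift and collapses quickly once the fold is reached.
    """
    half = traj.t >= traj.t[-1] / 2
    t, phi = traj.t[half], traj.phi[half]
    cyc = _detect_cycles(t, phi)
    if cyc is None or len(cyc["peaks"]) < 4:
        raise ValueError("fewer than 3 complete cycles detected")
    peaks = cyc["peaks"][-(n_cycles + 1):]
    troughs = cyc["troughs"]
    rises, falls, amps = [], [], []
    for a, b in zip(peaks[:-1], peaks[1:]):
        mid = troughs[(troughs > a) & (troughs < b)]
        if len(mid) != 1:
            continue
        m = mid[0]
        falls.append(t[m] - t[a])
        rises.append(t[b] - t[m])
        amps.append(0.5 * (phi[a] + phi[b]) - phi[m])
    if len(rises) < 3:
        raise ValueError("fewer than 3 complete cycles detected")
    periods = np.diff(t[peaks])
    return {
        "period": float(np.mean(periods)),
        "period_std": float(np.std(periods)),
        "amplitude": float(np.mean(amps)),
        "rise_time": float(np.mean(rises)),
        "fall_time": float(np.mean(falls)),
        "rise_fall_ratio": float(np.mean(rises) / np.mean(falls)),
    }


def phase_portrait(
    p: DimensionlessParams,
    initials,
    t_end: float = 500.0,
    dt: float = 0.01,
    store_every: int = 10,
) -> list[Trajectory]:
    """Orbits in the (phi, mu) plane from a list of initial conditions."""
    proto = StimulusProtocol(kind="constant", base_level=p.alpha)
    return [
        integrate_rk4(init, p, proto, t_end=t_end, dt=dt, store_every=store_every)
        for init in initials
    ]


def response_stats(traj: Trajectory, window: tuple[float, float]) -> dict:
    """Sample mean and standard deviation of phi over a time window."""
    mask = traj.window(*window)
    if not np.any(mask):
        raise ValueError(f"window {window} contains no samples")
    x = traj.phi[mask]
    return {
        "mean": float(np.mean(x)),
        "std": float(np.std(x)),
        "cv": float(np.std(x) / np.mean(x)) if np.mean(x) > 0 else float("nan"),
        "n": int(x.size),
    }


# ---------------------------------------------------------------------------
# vectorized batch integrator (internal): many cells / parameter points at
# once, used by the regime classifier and the phase-diagram grids
# ---------------------------------------------------------------------------

def _batch_rk4(
    phi0: np.ndarray,
    mu0: np.ndarray,
    alpha_of_t,
    kappa,
    gamma,
    beta,
    eps,
    t_end: float,
    dt: float,
    record_every: int = 10,
):
    """RK4 on a vector of cells with per-cell parameters.

    ``alpha_of_t(t)`` must return a scalar or per-cell vector.  Returns
    (times, phi_history, final_phi, final_mu) with the history decimated by
    ``record_every``.  States are clamped at zero before each step.
    """
    phi = np.array(phi0, dtype=float)
    mu = np.array(mu0, dtype=float)
    kappa, gamma = np.asarray(kappa, float), np.asarray(gamma, float)
    beta, eps = np.asarray(beta, float), np.asarray(eps, float)
    n = int(round(t_end / dt))

    def f(ph, m, a):
        ph = np.maximum(ph, 0.0)
        m = np.maximum(m, 0.0)
        d = 1.0 + ph * ph + gamma * m
        return a + kappa * ph * ph / d - ph, eps * (beta + ph - m)

    n_rec = n // record_every
    times = np.empty(n_rec)
    hist = np.empty((n_rec, phi.size))
    r = 0
    for k in range(n):
        t = k * dt
        if k % record_every == 0 and r < n_rec:
            times[r] = t
            hist[r] = phi
            r += 1
        np.maximum(phi, 0.0, out=phi)
        np.maximum(mu, 0.0, out=mu)
        a0 = alpha_of_t(t)
        am = alpha_of_t(t + 0.5 * dt)
        a1 = alpha_of_t(t + dt)
        k1p, k1m = f(phi, mu, a0)
        k2p, k2m = f(phi + 0.5 * dt * k1p, mu + 0.5 * dt * k1m, am)
        k3p, k3m = f(phi + 0.5 * dt * k2p, mu + 0.5 * dt * k2m, am)
        k4p, k4m = f(phi + dt * k3p, mu + dt * k3m, a1)
        phi = phi + dt / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p)
        mu = mu + dt / 6.0 * (k1m + 2 * k2m + 2 * k3m + k4m)
    return times[:r], hist[:r], phi, mu
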