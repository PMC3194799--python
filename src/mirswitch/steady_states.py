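"""Fixed points of the dimensionless switch model and their stability.

Setting the miRNA equation to zero gives the affine steady-state relation
``mu* = phi* + beta`` (the two modules differ by a constant at any fixed
point).  Substituting it into the protein equation and clearing the
denominator turns the fixed-point problem into a real cubic in ``phi``::

    -phi**3 + (alpha - Gamma + kappa)*phi**2
            + (alpha*Gamma - 1 - Gamma*beta)*phi
            + alpha*(1 + Gamma*beta) = 0

so the model has one, two (fold-degenerate) or three physical fixed points.
Roots are found globally from the companion matrix and polished by Newton
iteration; stability comes from the analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import DimensionlessParams, jacobian, rhs_dimensionless

__all__ = [
    "SteadyState",
    "mu_of_phi_steady",
    "steady_state_polynomial",
    "solve_steady_states",
    "classify_stability",
    "phi_cap",
    "steady_state_table",
]

_BRANCHES = {1: ("off",), 2: ("off", "on"), 3: ("off", "middle", "on")}


@dataclass(frozen=True)
class SteadyState:
    phi_star: float
    mu_star: float
    eigenvalues: tuple[complex, complex]
    stability: str  # stable_node | stable_focus | saddle | unstable_node | unstable_focus
    branch: str  # off | middle | on, by phi* rank
    marginal: bool = False  # |Re(eig)| below tolerance: label not trustworthy
    fold_degenerate: bool = False  # double root at a saddle-node

    @property
    def stable(self) -> bool:
        return self.stability in ("stable_node", "stable_focus")


def mu_of_phi_steady(phi, p: DimensionlessParams):
    """Steady-state miRNA level implied by a protein level (mu = phi + beta)."""
    return np.asarray(phi, float) + p.beta


def steady_state_polynomial(p: DimensionlessParams, alpha: float | None = None) -> np.ndarray:
    """Coefficients (descending) of the cubic whose roots are the fixed points."""
    a = p.alpha if alpha is None else alpha
    return np.array(
        [
            -1.0,
            a - p.gamma + p.kappa,
            a * p.gamma - 1.0 - p.gamma * p.beta,
            a * (1.0 + p.gamma * p.beta),
        ]
    )


def classify_stability(eigenvalues, marginal_tol: float = 1e-10) -> tuple[str, bool]:
    """Stability label from the eigenvalue pair, plus a marginality flag.

    The flag is raised whenever a real part sits within ``marginal_tol`` of
    zero, in which case the sign-based label is reported but should not be
    trusted (the point is at or next to a bifurcation).
    """
    e1, e2 = eigenvalues
    re = np.array([e1.real, e2.real])
    marginal = bool(np.any(np.abs(re) < marginal_tol))
    complex_pair = abs(e1.imag) > 0 or abs(e2.imag) > 0
    if np.all(re < 0):
        label = "stable_focus" if complex_pair else "stable_node"
    elif np.all(re > 0):
        label = "unstable_focus" if complex_pair else "unstable_node"
    else:
        label = "saddle"
    return label, marginal


def phi_cap(p: DimensionlessParams) -> float:
    """Upper bound on any physical steady-state phi, used by grid oracles.

    Production is bounded by alpha + kappa, so every fixed point satisfies
    phi* <= alpha_max + kappa; a tenfold margin keeps scans safely global.
    """
    return 10.0 * max(p.alpha_range[1], p.kappa, 1.0)


def _phi_residual(phi: float, p: DimensionlessParams, alpha: float) -> float:
    dphi, _ = rhs_dimensionless((phi, phi + p.beta), p, alpha_override=alpha)
    return float(dphi)


def _polish(phi: float, p: DimensionlessParams, alpha: float, tol: float = 1e-12) -> float:
    """Bounded scalar Newton polish of a cubic root on the steady-state curve."""
    x = phi
    for _ in range(50):
        f = _phi_residual(x, p, alpha)
        D = 1.0 + x**2 + p.gamma * (x + p.beta)
        df = 2.0 * p.kappa * x * (1.0 + p.gamma * (x + p.beta)) / D**2 \
            - p.kappa * x**2 * p.gamma / D**2 - 1.0
        if df == 0.0:
            break
        step = f / df
        if abs(step) > 1.0:  # keep the polish local to the companion root
            step = np.sign(step)
        x -= step
        if abs(step) < tol:
            break
    return x


def solve_steady_states(p: DimensionlessParams, alpha: float | None = None) -> list[SteadyState]:
    """All physical fixed points, sorted by phi*, with stability attached.

    Real cubic roots with phi >= -1e-9 are clamped to zero, polished, and
    de-duplicated within 1e-7.  A de-duplicated double root (the system at
    a fold) is reported as two entries sharing ``fold_degenerate=True``.

    ``alpha`` overrides the stimulus level of ``p`` without rebuilding the
    parameter object; it may be negative, which the bifurcation module uses
    to locate folds outside the physical stimulus window.
    """
    q = p
    a = p.alpha if alpha is None else float(alpha)
    coeffs = steady_state_polynomial(q, alpha=a)
    roots = np.roots(coeffs)
    scale = max(1.0, float(np.max(np.abs(roots))) if roots.size else 1.0)
    real = [r.real for r in roots if abs(r.imag) <= 1e-7 * scale]
    real = [_polish(x, q, a) for x in real]
    physical = sorted(x if x > 0 else 0.0 for x in real if x >= -1e-9)

    # de-duplicate, remembering multiplicity for the fold-degenerate flag
    unique: list[float] = []
    counts: list[int] = []
    for x in physical:
        if unique and abs(x - unique[-1]) < 1e-7:
            counts[-1] += 1
        else:
            unique.append(x)
            counts.append(1)
    if not unique:
        if a >= 0:
            raise RuntimeError(
                "no physical steady state found; this cannot occur for valid "
                f"non-negative parameters ({q!r})"
            )
        return []  # negative (diagnostic) stimulus may push all roots below 0

    expanded: list[tuple[float, bool]] = []
    for x, c in zip(unique, counts):
        if c > 1:
            expanded.extend([(x, True)] * min(c, 2))
        else:
            expanded.append((x, False))

    branches = _BRANCHES.get(len(expanded))
    if branches is None:  # >3 impossible for a cubic; guard anyway
        raise RuntimeError(f"unexpected number of fixed points: {len(expanded)}")

    out = []
    for (x, degenerate), branch in zip(expanded, branches):
        mu = float(mu_of_phi_steady(x, q))
        eig = np.linalg.eigvals(jacobian((x, mu), q))
        label, marginal = classify_stability((complex(eig[0]), complex(eig[1])))
        out.append(
            SteadyState(
                phi_star=float(x),
                mu_star=mu,
                eigenvalues=(complex(eig[0]), complex(eig[1])),
                stability=label,
                branch=branch,
                marginal=marginal or degenerate,
                fold_degenerate=degenerate,
            )
        )
    return out


def steady_state_table(p: DimensionlessParams, states: list[SteadyState]) -> pd.DataFrame:
    """Long-format table of a steady-state set (one row per fixed point)."""
    import hashlib

    key = f"{p.alpha}|{p.beta}|{p.kappa}|{p.gamma}|{p.epsilon}"
    h = hashlib.sha1(key.encode()).hexdigest()[:10]
    rows = [
        {
            "param_hash": h,
            "alpha": p.alpha,
            "phi_star": s.phi_star,
            "mu_star": s.mu_star,
            "re_eig1": s.eigenvalues[0].real,
            "im_eig1": s.eigenvalues[0].imag,
            "re_eig2": s.eigenvalues[1].real,
            "im_eig2": s.eigenvalues[1].imag,
            "stability": s.stability,
            "branch": s.branch,
        }
        for s in states
    ]
    return pd.DataFrame(rows)
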