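"""Core equations of the Myc/E2F/miR-17-92 switch model.

The network couples an autocatalytic protein module (Myc and the E2F
transcription factors, lumped into a single variable) with the miR-17-92
miRNA cluster.  The protein module activates itself through a saturating,
second-order positive feedback and also drives transcription of the miRNA
cluster, which in turn inhibits protein expression -- a positive loop
interlinked with a negative one.

Dimensional form (concentrations ``P`` for protein, ``m`` for miRNA)::

    dP/dt = a + k * P**2 / (K1*K2 + P**2 + g*m) - gamma_p * P
    dm/dt = b + r * P - gamma_m * m

Dimensionless form (phi = P/P0, mu = m/m0, tau = gamma_p * t)::

    dphi/dtau = alpha + kappa * phi**2 / (1 + phi**2 + Gamma*mu) - phi
    dmu/dtau  = epsilon * (beta + phi - mu)

with P0 = sqrt(K1*K2), m0 = (r/gamma_m)*P0 and

    alpha   = a / (gamma_p * P0)        constitutive protein input
    kappa   = k / (gamma_p * P0)        positive-feedback strength
    Gamma   = g * r / (gamma_m * P0)    miRNA-inhibition strength
    beta    = b / (r * P0)              constitutive miRNA transcription
    epsilon = gamma_m / gamma_p         miRNA/protein degradation-rate ratio

``epsilon`` is the timescale ratio of the two modules; it is typically well
below 1 because miRNAs are more stable than proteins, which makes the miRNA
loop the slow arm of the switch.

Every other module consumes the right-hand sides and the Jacobian defined
here; the algebra appears in this file only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DimensionalParams",
    "DimensionlessParams",
    "State",
    "REFERENCE",
    "rhs_dimensional",
    "rhs_dimensionless",
    "jacobian",
    "nondimensionalize",
]

#: Physical window of the stimulus parameter alpha used for sweeps and for
#: the one-way-switch diagnosis (folds below the lower edge are unreachable).
DEFAULT_ALPHA_RANGE = (0.0, 0.3)


def _check_finite(*values: float) -> None:
    arrs = [np.asarray(v, dtype=float) for v in values]
    if not all(np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("state values must be finite")


@dataclass(frozen=True)
class DimensionalParams:
    """Rate constants of the dimensional model, all non-negative.

    ``saturation_consts`` are the two concentration-scale constants of the
    autocatalytic term (their product sets the half-saturation scale);
    ``mirna_inhibition_const`` weights the miRNA term in the same
    denominator.  Degradation rates must be strictly positive.
    """

    basal_protein_rate: float
    autocatalysis_const: float
    saturation_consts: tuple[float, float]
    mirna_inhibition_const: float
    basal_mirna_rate: float
    protein_driven_mirna_rate: float
    protein_degradation_rate: float
    mirna_degradation_rate: float

    def __post_init__(self) -> None:
        fields = {
            "basal_protein_rate": self.basal_protein_rate,
            "autocatalysis_const": self.autocatalysis_const,
            "mirna_inhibition_const": self.mirna_inhibition_const,
            "basal_mirna_rate": self.basal_mirna_rate,
            "protein_driven_mirna_rate": self.protein_driven_mirna_rate,
            "protein_degradation_rate": self.protein_degradation_rate,
            "mirna_degradation_rate": self.mirna_degradation_rate,
        }
        for name, value in fields.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if len(self.saturation_consts) != 2 or any(
            not np.isfinite(s) or s <= 0 for s in self.saturation_consts
        ):
            raise ValueError("saturation_consts must be two positive constants")
        if self.protein_degradation_rate <= 0 or self.mirna_degradation_rate <= 0:
            raise ValueError("degradation rates must be > 0")


@dataclass(frozen=True)
class DimensionlessParams:
    """The five dimensionless parameters (alpha, beta, kappa, Gamma, epsilon).

    ``gamma = 0`` is legal and removes miRNA inhibition entirely.
    ``alpha_range`` is the physically admissible stimulus window.
    """

    alpha: float
    beta: float
    kappa: float
    gamma: float
    epsilon: float
    alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "kappa", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not np.isfinite(self.epsilon) or self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon!r}")
        lo, hi = self.alpha_range
        if not lo < hi:
            raise ValueError("alpha_range must be an increasing pair")
        if not (lo - 1e-12 <= self.alpha <= hi + 1e-12):
            raise ValueError(
                f"alpha={self.alpha} outside alpha_range={self.alpha_range}"
            )

    def with_alpha(self, alpha: float) -> "DimensionlessParams":
        """Copy of the parameter set at a different stimulus level."""
        lo, hi = self.alpha_range
        rng = (min(lo, alpha), max(hi, alpha))
        return replace(self, alpha=alpha, alpha_range=rng)


@dataclass(frozen=True)
class State:
    """Dimensionless concentrations of the protein module and the miRNA."""

    phi: float
    mu: float

    def __post_init__(self) -> None:
        _check_finite(self.phi, self.mu)


#: Reference configuration of the dimensionless model: positive-feedback
#: strength in the bistable range, basal miRNA transcription beta, and a
#: slow miRNA loop (epsilon << 1).  All worked examples, regime maps and
#: ensemble runs in this package start from this set unless stated
#: otherwise; see docs/methods.md for how it was fixed.
REFERENCE = DimensionlessParams(
    alpha=0.04, beta=0.2, kappa=3.5, gamma=1.0, epsilon=0.02
)


def _split_state(state) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(state, State):
        return np.asarray(state.phi, float), np.asarray(state.mu, float)
    phi, mu = state
    return np.asarray(phi, float), np.asarray(mu, float)


def rhs_dimensional(state, p: DimensionalParams):
    """Time derivatives (dP/dt, dm/dt) of the dimensional model."""
    P, m = _split_state(state)
    _check_finite(P, m)
    K1, K2 = p.saturation_consts
    denom = K1 * K2 + P**2 + p.mirna_inhibition_const * m
    dP = (
        p.basal_protein_rate
        + p.autocatalysis_const * P**2 / denom
        - p.protein_degradation_rate * P
    )
    dm = (
        p.basal_mirna_rate
        + p.protein_driven_mirna_rate * P
        - p.mirna_degradation_rate * m
    )
    return dP, dm


def rhs_dimensionless(state, p: DimensionlessParams, alpha_override: float | None = None):
    """Derivatives (dphi/dtau, dmu/dtau) of the dimensionless model.

    ``alpha_override`` substitutes a time-varying stimulus value for
    ``p.alpha`` without rebuilding the parameter object; it is the hook the
    integrators use to drive the system with a protocol.
    """
    phi, mu = _split_state(state)
    _check_finite(phi, mu)
    alpha = p.alpha if alpha_override is None else alpha_override
    denom = 1.0 + phi**2 + p.gamma * mu
    dphi = alpha + p.kappa * phi**2 / denom - phi
    dmu = p.epsilon * (p.beta + phi - mu)
    return dphi, dmu


def jacobian(state, p: DimensionlessParams) -> np.ndarray:
    """Analytic Jacobian of the dimensionless right-hand side.

    With D = 1 + phi**2 + Gamma*mu::

        d(dphi)/dphi = 2*kappa*phi*(1 + Gamma*mu)/D**2 - 1
        d(dphi)/dmu  = -kappa*Gamma*phi**2/D**2
        d(dmu)/dphi  = epsilon
        d(dmu)/dmu   = -epsilon
    """
    phi, mu = _split_state(state)
    _check_finite(phi, mu)
    D = 1.0 + phi**2 + p.gamma * mu
    a11 = 2.0 * p.kappa * phi * (1.0 + p.gamma * mu) / D**2 - 1.0
    a12 = -p.kappa * p.gamma * phi**2 / D**2
    return np.array([[a11, a12], [p.epsilon, -p.epsilon]], dtype=float)


def nondimensionalize(
    p: DimensionalParams,
) -> tuple[DimensionlessParams, dict[str, float]]:
    """Map dimensional rates to the five dimensionless parameters.

    Returns the parameter set together with the scale factors, keyed
    ``protein_scale`` (P0), ``mirna_scale`` (m0) and ``time_scale``
    (1/gamma_p), so that ``phi = P/P0``, ``mu = m/m0`` and
    ``tau = t/time_scale`` map a dimensional trajectory onto the
    dimensionless one exactly.
    """
    K1, K2 = p.saturation_consts
    gp = p.protein_degradation_rate
    gm = p.mirna_degradation_rate
    P0 = float(np.sqrt(K1 * K2))
    m0 = p.protein_driven_mirna_rate / gm * P0
    if m0 <= 0:
        raise ValueError(
            "protein_driven_mirna_rate must be > 0 to define the miRNA scale"
        )
    alpha = p.basal_protein_rate / (gp * P0)
    kappa = p.autocatalysis_const / (gp * P0)
    gamma = p.mirna_inhibition_const * p.protein_driven_mirna_rate / (gm * P0)
    beta = p.basal_mirna_rate / (p.protein_driven_mirna_rate * P0)
    epsilon = gm / gp
    lo, hi = DEFAULT_ALPHA_RANGE
    rng = (min(lo, alpha), max(hi, 1.5 * alpha if alpha > 0 else hi))
    dimless = DimensionlessParams(
        alpha=alpha, beta=beta, kappa=kappa, gamma=gamma, epsilon=epsilon,
        alpha_range=rng,
    )
    scales = {"protein_scale": P0, "mirna_scale": m0, "time_scale": 1.0 / gp}
    return dimless, scales
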