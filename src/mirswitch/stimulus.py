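"""Stimulus protocols: the synthetic input signals driving the switch.

The stimulus is the constitutive protein input alpha.  Protocols are
piecewise-constant in time (constant, rectangular pulse, step) and may carry
additive Gaussian white noise, ``alpha_n(t) = alpha(t) + xi(t)``, entering
the protein equation only.  ``noise_variance`` is the white-noise intensity
sigma^2 (spectral density): over a step of length dt the integrated noise
contribution has variance sigma^2 * dt, so the per-step stimulus offset is
``sigma * z / sqrt(dt)`` with ``z ~ N(0, 1)``.

Noise realizations are never stored; a seed plus sigma^2 regenerates them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["StimulusProtocol", "noise_increments", "KINDS"]

KINDS = ("constant", "pulse", "step", "noisy_step", "noisy_constant")


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant stimulus specification.

    ``amplitude`` is the absolute stimulus level inside the pulse window or
    after the step (not an increment over ``base_level``).  Evaluation is
    right-continuous: at exactly ``t_on`` the post-transition value applies,
    and a pulse returns to ``base_level`` at exactly ``t_off``.
    """

    kind: str
    base_level: float
    amplitude: float = 0.0
    t_on: float = 0.0
    t_off: float = 0.0
    noise_variance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}; one of {KINDS}")
        if self.base_level < 0:
            raise ValueError("base_level must be >= 0")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if self.kind == "pulse" and not self.t_on < self.t_off:
            raise ValueError("pulse requires t_on < t_off")
        if self.kind in ("noisy_step", "noisy_constant") and self.noise_variance == 0:
            # legal but almost certainly a configuration slip
            pass

    # -- deterministic part -------------------------------------------------
    def evaluate(self, t):
        """Deterministic stimulus value(s) at time(s) ``t`` (pure function)."""
        t = np.asarray(t, dtype=float)
        if self.kind in ("constant", "noisy_constant"):
            out = np.full_like(t, self.base_level)
        elif self.kind == "pulse":
            out = np.where(
                (t >= self.t_on) & (t < self.t_off), self.amplitude, self.base_level
            )
        elif self.kind in ("step", "noisy_step"):
            out = np.where(t >= self.t_on, self.amplitude, self.base_level)
        else:  # pragma: no cover
            raise AssertionError(self.kind)
        return float(out) if out.ndim == 0 else out

    def __call__(self, t):
        return self.evaluate(t)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
        return cls(**d)


def noise_increments(n_steps: int, dt: float, sigma2: float, seed: int) -> np.ndarray:
    """Per-step white-noise stimulus offsets xi_k for a fixed-step integrator.

    Each entry is ``sqrt(sigma2/dt) * z_k`` with independent standard-normal
    ``z_k``; adding ``xi_k`` to alpha over a step of length ``dt`` yields an
    additive diffusion of intensity sigma2 in the protein equation.  The same
    seed always returns the identical array.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0:
        return np.zeros(n_steps)
    rng = np.random.default_rng(seed)
    return np.sqrt(sigma2 / dt) * rng.standard_normal(n_steps)
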