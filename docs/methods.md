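# Methods

## Model

The package analyses a two-variable reduction of the mammalian G1–S
regulatory network in which the Myc and E2F transcription factors are lumped
into one autocatalytic protein module and the miR-17-92 cluster into one
miRNA module. The protein module activates itself (the E2F/Myc positive
feedback loops), transcribes the miRNA, and is translationally inhibited by
it — a positive loop interlinked with a negative one.

Dimensionless equations (phi: protein, mu: miRNA, tau: time in units of the
protein lifetime):

    dphi/dtau = alpha + kappa * phi^2 / (1 + phi^2 + Gamma * mu) - phi
    dmu/dtau  = epsilon * (beta + phi - mu)

| parameter | meaning | default | units |
|---|---|---|---|
| alpha   | constitutive protein input (serum/growth-factor controlled stimulus) | 0.04 (basal), window [0, 0.3] | – |
| beta    | constitutive (protein-independent) miRNA transcription | 0.2 | – |
| kappa   | strength of the autocatalytic positive feedback | 3.5 | – |
| Gamma   | strength of miRNA inhibition of protein expression | 0–2 (swept) | – |
| epsilon | gamma_m / gamma_p, the miRNA-to-protein degradation-rate ratio | 0.02 (slow-loop comparison: 0.2) | – |

Because miRNAs outlive proteins, epsilon << 1: the miRNA loop is the slow
arm and the protein loop the fast arm of a dual-time switch. At any fixed
point the miRNA balance gives the affine relation mu* = phi* + beta, so the
fixed-point problem reduces to a real cubic in phi and the model has one,
two (at a fold) or three physical steady states. The lowest-phi state is
the off-state (quiescence), the highest the on-state.

The dimensional form (`DimensionalParams`) carries explicit production,
saturation and degradation constants; `nondimensionalize` maps it onto the
five parameters above with protein scale P0 = sqrt(K1*K2), miRNA scale
m0 = (r/gamma_m) P0 and time scale 1/gamma_p, and the round trip is tested
to 1e-6 on trajectories.

### Reference configuration

The defaults above are the package's reference study conditions. They were
fixed once, before any test was written against them, by requiring the full
qualitative repertoire of the network simultaneously:

- Gamma = 0 (no miRNA): only one-way switching in the physical stimulus
  window (the deactivating fold sits at negative alpha) and no Hopf points;
- Gamma = 1.0 at basal alpha = 0.04: bistable; the reference stimulus pulse
  to 0.16 during [20, 25] drives an irreversible switch;
- Gamma = 1.2 at alpha = 0.04: three fixed points with only the off-state
  stable — excitable (pulse, excursion, full recovery);
- Gamma = 1.6: exactly two Hopf points in [0, 0.3], with the constant
  stimulus 0.16 strictly between them — relaxation oscillation;
- the Gamma–alpha plane at kappa = 3.5 carries exactly the four regimes
  monostable / bistable / excitable / oscillatory.

Raising kappa at fixed Gamma stages monostable → bistable switch → one-way
switch; raising Gamma turns the one-way switch reversible inside the
physical window (the bistable-switch interval grows from zero).

## Steady states and stability

Roots come from the companion matrix of the cleared cubic and are polished
by a bounded Newton iteration (tolerance 1e-12), clamped at phi >= 0 and
de-duplicated within 1e-7; a de-duplicated double root is flagged
fold-degenerate. Stability is read off the analytic 2x2 Jacobian:
negative real parts → stable node/focus, mixed signs → saddle, positive →
unstable node/focus; a real part within 1e-10 of zero raises an explicit
marginal flag instead of a silent label. An independent dense-grid
sign-change oracle (1e5 points up to phi_cap = 10*max(alpha_max, kappa))
cross-checks the solver on hundreds of random parameter sets in the tests.

## Bifurcation analysis

One-parameter sweeps re-solve the cubic globally at every stimulus value —
with a two-variable model and a scalar polynomial, dense re-solving is
cheaper and strictly more robust than arclength continuation, and cannot
lose a branch. Folds are bisected on changes of the *real* root count
(sign-independent, so a root crossing phi = 0 is not mistaken for a fold,
and folds at negative, unphysical stimulus — the one-way signature — are
still found) to a 1e-8 bracket. Hopf points are bisected on the sign of the
leading eigenvalue real part along phi-rank-linked branches, and only count
when the pair is complex (|Im| > 1e-6).

Regime classification at a point: two stable states → bistable; one stable
plus two unstable → excitable if a standard test pulse (rectangular,
5 time units, 0.16 above the resting stimulus) drives phi above the
middle-branch value and the system then returns within 1e-3 of rest;
no stable state → oscillatory if a 2000-time-unit run (first half
discarded) shows >= 3 peaks with < 5% period dispersion and amplitude
> 1e-3; otherwise monostable, with an explicit `unclassified` label when a
simulation-based check is inconclusive. The oscillation probe starts 0.3
away from the focus because weakly unstable spirals just past a Hopf point
grow at rates ~1e-3 and an infinitesimal kick would not clear the transient
within any reasonable run; the verification window is 2000 time units
because the relaxation period is ~170 time units at epsilon = 0.02 (it
scales with the slow-loop time 1/epsilon).

Hysteresis runs integrate a triangular stimulus ramp at 2e-5 per time unit
(quasi-static against both loop timescales); a jump is scored where
|dphi/dalpha| exceeds 100 (quasi-static branch slopes are O(10), fold
transitions orders of magnitude steeper). The fold-ghost delay scales like
ramp_rate^(2/3), and at the default rate the jump locations agree with the
bisected folds to ~1%.

## Stimulus generator

Protocols are piecewise-constant (constant, pulse, step), right-continuous
at discontinuities, with `amplitude` the absolute level inside the pulse
window or after the step. Noise is additive Gaussian white noise on the
stimulus only, alpha_n(t) = alpha(t) + xi(t), with intensity sigma^2
(spectral density): a fixed-step integrator draws sigma/sqrt(dt) * z once
per step, so the integrated contribution over t has variance sigma^2 * t.
The fluctuating stimulus is deliberately not clipped at zero (clipping
would bias the stated zero-mean noise); the *state* is clamped at zero
before each derivative evaluation instead, and every clamp event is
counted in the run metadata. Noise arrays are never stored — seeds and
sigma^2 regenerate them exactly.

What the generator emulates: an extracellular stimulus fluctuating fast
compared with every cellular timescale, identical in law across a cell
population but independent per cell. What it does not emulate: intrinsic
(birth–death) noise, transcriptional bursting, colored extrinsic noise,
or cell-to-cell parameter variability. Passing ensemble tests therefore
demonstrate noise-driven escape over a deterministic basin boundary, not a
full stochastic gene-expression model.

## Integration

Deterministic runs use the classical fixed-step fourth-order Runge–Kutta
scheme, dt = 0.01 by default (halving dt changes pulse-response
trajectories by < 1e-6; measured convergence order ~4.0 on the linear
decay problem). The stimulus is evaluated at stage times with the
right-continuous convention.

Stochastic runs use the same fourth-order stepper with the per-step noise
offset frozen across the four stages — for purely additive noise this is
deterministic-order-4, strong-order-1 in the noise, and reduces *exactly*
(bitwise) to the deterministic integrator at sigma = 0. Default dt = 0.002.
Validation: stationary variance of the kappa = 0 linear submodel (an
Ornstein–Uhlenbeck process) within 5% of sigma^2/2 over 4000 time units,
and Kolmogorov–Smirnov indistinguishability (1% level) from an
Euler–Maruyama oracle run at a 50-fold finer step.

## Ensembles

`run_ensemble` settles N cells at the on-state fixed point (the base
stimulus must admit three fixed points, otherwise there is no on-to-off
escape to measure) and drives each with an independent noise stream (cell
seed = base_seed + index, recorded in metadata). A cell "has transitioned"
when phi first falls below the unstable middle-branch phi* at the
deterministic base stimulus (separatrix proxy; a midpoint rule is available
as an option). F(t) is the at-least-once (first-passage) fraction, hence
nondecreasing; the instantaneous-occupancy variant is reported alongside.
F_s is the mean of F over the final 10% of the run with a plateau check
(|slope| <= 1e-4 per time unit, else flagged non-converged but still
reported); T_R is the linearly interpolated first time F reaches
(F(0) + F_s)/2.

Reference ensemble conditions: N = 200 cells, base stimulus alpha = 0.08
(inside the bistable window), sigma^2 = 0.01 for the Gamma and alpha
sweeps, sigma^2 = 0.02 for the epsilon comparison at Gamma = 1.1 (chosen so
both the fast and the slow loop actually flip there), t_end = 100–120.
Measured behavior: F_s falls monotonically with alpha (deeper on-state
basin) and rises monotonically with Gamma (stronger inhibition pulls the
on-state toward the separatrix — this is the miRNA-enabled recovery from
the on-state to quiescence); the fast loop (epsilon = 0.02) has the shorter
response time, while the slow loop (epsilon = 0.2) buffers on-state
fluctuations (phi standard deviation roughly 2.5x smaller at Gamma = 1.2,
sigma^2 = 0.01).

## Numerical choices and degenerate cases

- Fold exactly at the lower stimulus edge: classified bistable_switch
  (boundary inclusive), a documented deterministic tie-break.
- Root de-duplication at 1e-7; fold brackets at 1e-8; Hopf crossings
  require |Im| > 1e-6 to exclude degenerate real crossings.
- phase-diagram boundary points are bisected per column on the analytic
  structure (root count for folds, eigenvalue sign for Hopf), so every
  boundary point separates two differently labelled cells.
- Ensemble sweep grid point j uses base seed base_seed + 7919*j, making
  tables reproducible from a single integer while keeping cells independent
  across points.

## Known limitations

- The classifier's simulation caps (2000 time units for cycles, 300 for
  pulse recovery) are tuned to epsilon >= 0.01; far smaller epsilon would
  need proportionally longer probes.
- No time-delay terms, no intrinsic noise, no multi-target miRNA network:
  the model is the two-variable reduction only.
- Plain Monte Carlo escape statistics; no Kramers-rate theory or importance
  sampling, so very rare escapes (F_s << 1/N) are simply reported as zero.
- The explicit radical expressions for the steady states are not exported
  symbolically; numeric roots (cross-checked by an independent scan) stand
  in for them.
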