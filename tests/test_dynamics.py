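"""Deterministic integration: accuracy, classification, waveform metrics."""

import numpy as np
import pytest

import mirswitch as ms
from mirswitch.dynamics import Trajectory


def _const_proto(level):
    return ms.StimulusProtocol(kind="constant", base_level=level)


def _synthetic_trajectory(phi, t, mu=None):
    return Trajectory(
        t=t, phi=phi, mu=np.zeros_like(t) if mu is None else mu,
        alpha=np.zeros_like(t), protocol=_const_proto(0.0),
        meta={"dt": t[1] - t[0]},
    )


class TestIntegrator:
    def test_fixed_point_is_stationary(self, ref):
        """Starting exactly at a stable fixed point drifts < 1e-8 in 100 units."""
        s = ms.solve_steady_states(ref)[0]
        traj = ms.integrate_rk4(
            (s.phi_star, s.mu_star), ref, _const_proto(ref.alpha),
            t_end=100.0, dt=0.01, store_every=100,
        )
        assert np.max(np.abs(traj.phi - s.phi_star)) < 1e-8

    def test_fourth_order_convergence(self, with_params):
        """Global error on the pure-decay problem shrinks ~16x per dt halving."""
        p = with_params(kappa=0.0, alpha=0.0)
        errors = []
        for dt in (0.04, 0.02, 0.01):
            traj = ms.integrate_rk4((1.0, 0.0), p, _const_proto(0.0),
                                    t_end=5.0, dt=dt)
            exact = np.exp(-traj.t)
            errors.append(np.max(np.abs(traj.phi - exact)))
        orders = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert np.all(orders >= 3.8)

    def test_divergence_aborts_with_diagnostic(self, ref):
        with pytest.raises((RuntimeError, ValueError)):
            ms.integrate_rk4((1e200, 0.0), ref, _const_proto(0.04),
                             t_end=1.0, dt=0.5)

    def test_bad_steps_rejected(self, ref):
        with pytest.raises(ValueError):
            ms.integrate_rk4((0.1, 0.1), ref, _const_proto(0.04), t_end=1.0, dt=0.0)


class TestResponseClassification:
    def test_subthreshold_pulse_returns(self, ref):
        """A pulse below the activating fold leaves the off-state untouched."""
        rest = ms.rest_state(ref)
        proto = ms.StimulusProtocol(
            kind="pulse", base_level=ref.alpha, amplitude=0.08, t_on=20, t_off=25
        )
        traj = ms.integrate_rk4((rest.phi_star, rest.mu_star), ref, proto,
                                t_end=250.0, dt=0.01, store_every=10)
        assert ms.classify_response(traj, ref) == "no_switch"

    def test_superthreshold_pulse_switches_irreversibly(self, ref):
        """The reference 0.16 pulse drives a one-way switch onto the on-branch."""
        rest = ms.rest_state(ref)
        proto = ms.StimulusProtocol(
            kind="pulse", base_level=ref.alpha, amplitude=0.16, t_on=20, t_off=25
        )
        traj = ms.integrate_rk4((rest.phi_star, rest.mu_star), ref, proto,
                                t_end=250.0, dt=0.01, store_every=10)
        assert ms.classify_response(traj, ref) == "irreversible_switch"
        on = ms.solve_steady_states(ref)[-1]
        assert traj.phi[-1] == pytest.approx(on.phi_star, abs=1e-3)

    def test_excitable_pulse_recovers(self, with_params):
        p = with_params(gamma=1.2)
        rest = ms.rest_state(p)
        proto = ms.StimulusProtocol(
            kind="pulse", base_level=p.alpha, amplitude=0.16, t_on=20, t_off=25
        )
        # the slow miRNA tail (1/epsilon = 50 time units) must fully relax
        # before the settle check accepts the rest state
        traj = ms.integrate_rk4((rest.phi_star, rest.mu_star), p, proto,
                                t_end=650.0, dt=0.01, store_every=10)
        assert ms.classify_response(traj, p) == "excitable_pulse"


class TestOscillationMetrics:
    def test_synthetic_sinusoid_period(self):
        t = np.arange(0, 200, 0.05)
        traj = _synthetic_trajectory(1.0 + 0.5 * np.sin(2 * np.pi * t / 13.0), t)
        m = ms.oscillation_metrics(traj)
        assert m["period"] == pytest.approx(13.0, rel=0.01)
        assert m["amplitude"] == pytest.approx(1.0, rel=0.05)
        assert m["rise_fall_ratio"] == pytest.approx(1.0, rel=0.05)

    def test_too_few_cycles_is_an_error(self):
        t = np.arange(0, 10, 0.05)
        traj = _synthetic_trajectory(np.sin(2 * np.pi * t / 8.0), t)
        with pytest.raises(ValueError):
            ms.oscillation_metrics(traj)

    def test_limit_cycle_period_is_stable(self, with_params):
        """Simulated relaxation cycles repeat with < 5% period dispersion."""
        p = with_params(gamma=1.6, alpha=0.16)
        s = ms.solve_steady_states(p)[0]
        traj = ms.integrate_rk4((s.phi_star + 0.3, s.mu_star), p,
                                _const_proto(0.16), t_end=1500.0, dt=0.02,
                                store_every=10)
        assert ms.classify_response(traj, p) == "sustained_oscillation"
        m = ms.oscillation_metrics(traj)
        assert m["period_std"] < 0.05 * m["period"]


class TestPhasePortrait:
    def test_stable_orbits_terminate_at_fixed_points(self, ref):
        states = ms.solve_steady_states(ref)
        orbits = ms.phase_portrait(ref, [(0.01, 0.1), (3.0, 3.0)], t_end=600.0)
        for orbit in orbits:
            end = (orbit.phi[-1], orbit.mu[-1])
            dmin = min(
                np.hypot(end[0] - s.phi_star, end[1] - s.mu_star) for s in states
            )
            assert dmin < 1e-4

    def test_oscillatory_orbits_share_one_cycle(self, with_params):
        """Two starts converge onto the same closed curve (gap < 2% amplitude)."""
        from scipy.signal import find_peaks

        p = with_params(gamma=1.6, alpha=0.16)
        orbits = ms.phase_portrait(p, [(0.2, 0.3), (2.5, 2.0)], t_end=1500.0)
        cycles = []
        for orbit in orbits:
            half = orbit.t >= orbit.t[-1] / 2
            phi, mu = orbit.phi[half], orbit.mu[half]
            peaks, _ = find_peaks(phi, prominence=0.5 * np.ptp(phi))
            seg = slice(peaks[-2], peaks[-1] + 1)  # one full peak-to-peak cycle
            cycles.append(np.column_stack([phi[seg], mu[seg]]))
        amp = np.ptp(cycles[0][:, 0])
        # closure: the cycle begins and ends at the same phase-space point
        for c in cycles:
            assert np.hypot(*(c[0] - c[-1])) < 0.01 * amp
        # pointwise proximity of the two cycles
        from scipy.spatial import cKDTree

        tree = cKDTree(cycles[1])
        dists, _ = tree.query(cycles[0])
        assert dists.max() < 0.02 * amp


class TestResponseStats:
    def test_constant_series_has_zero_std(self):
        t = np.arange(0, 10, 0.1)
        traj = _synthetic_trajectory(np.full_like(t, 1.7), t)
        st = ms.response_stats(traj, (2.0, 8.0))
        assert st["std"] == 0.0 and st["mean"] == 1.7

    def test_empty_window_is_an_error(self):
        t = np.arange(0, 10, 0.1)
        traj = _synthetic_trajectory(t * 0, t)
        with pytest.raises(ValueError):
            ms.response_stats(traj, (20.0, 30.0))

    def test_white_noise_moments_recovered(self):
        """Moments of a generated white-noise series match its parameters."""
        dt, sigma2, n = 0.002, 0.01, 200_000
        xi = ms.noise_increments(n, dt, sigma2, seed=9)
        t = dt * np.arange(n)
        traj = _synthetic_trajectory(xi, t)
        st = ms.response_stats(traj, (0.0, n * dt))
        expected_std = np.sqrt(sigma2 / dt)
        assert abs(st["mean"]) < 4 * expected_std / np.sqrt(n)
        assert st["std"] == pytest.approx(expected_std, rel=0.02)


def test_faster_loop_reaches_midpoint_sooner(with_params):
    """Under the step stimulus the smaller-epsilon loop rises strictly faster."""
    times = {}
    for eps in (0.02, 0.2):
        p = with_params(epsilon=eps)
        rest = ms.rest_state(p)
        proto = ms.StimulusProtocol(kind="step", base_level=p.alpha,
                                    amplitude=0.16, t_on=50.0)
        traj = ms.integrate_rk4((rest.phi_star, rest.mu_star), p, proto,
                                t_end=250.0, dt=0.01, store_every=10)
        on = ms.solve_steady_states(p.with_alpha(0.16))[-1].phi_star
        target = rest.phi_star + 0.5 * (on - rest.phi_star)
        hit = traj.t[(traj.t > 50.0) & (traj.phi >= target)][0]
        times[eps] = hit - 50.0
    assert times[0.02] < times[0.2]
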