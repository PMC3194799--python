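"""Sweeps, fold/Hopf location, switch character, regime maps, hysteresis."""

import dataclasses

import numpy as np
import pytest

import mirswitch as ms
from mirswitch.steady_states import solve_steady_states


GRID = np.linspace(0.0, 0.3, 151)


class TestSweep:
    def test_monostable_sweep_is_featureless(self, with_params):
        p = with_params(kappa=2.0)
        d = ms.sweep_alpha(p, GRID)
        assert np.all(d.counts() == 1)
        assert d.saddle_nodes == [] and d.hopf_points == []
        assert d.switch_character == "monostable"

    def test_grid_contract(self, ref):
        with pytest.raises(ValueError):
            ms.sweep_alpha(ref, np.linspace(0, 0.3, 20))
        with pytest.raises(ValueError):
            ms.sweep_alpha(ref, GRID[::-1])

    def test_counts_match_oracle_at_each_alpha(self, with_params):
        p = with_params(gamma=1.6)
        d = ms.sweep_alpha(p, GRID)
        for a, states in zip(d.alpha_grid[::10], d.states[::10]):
            assert len(states) == len(solve_steady_states(p, alpha=a))


class TestSaddleNodes:
    def test_bistable_set_has_two_enclosing_folds(self, with_params):
        """A bistable window is enclosed by exactly two saddle-node points."""
        p = with_params(gamma=1.6)
        d = ms.sweep_alpha(p, GRID)
        assert len(d.saddle_nodes) == 2
        lo, hi = (b.alpha_at for b in d.saddle_nodes)
        assert lo < hi
        mid_count = len(solve_steady_states(p, alpha=0.5 * (lo + hi)))
        assert mid_count == 3
        for b in d.saddle_nodes:
            assert b.bracket_width <= 1e-8

    def test_fold_locations_match_dense_scan(self, with_params):
        """Bisected folds agree with a 10^4-point dense count scan to 1e-4."""
        p = with_params(gamma=1.6)
        d = ms.sweep_alpha(p, GRID)
        dense = np.linspace(0.0, 0.3, 10_000)
        counts = np.array([len(solve_steady_states(p, alpha=a)) for a in dense])
        change = dense[:-1][np.diff(counts) != 0] + 0.5 * (dense[1] - dense[0])
        assert len(change) == len(d.saddle_nodes)
        for b, a_ref in zip(d.saddle_nodes, change):
            assert b.alpha_at == pytest.approx(a_ref, abs=1e-4)


class TestHopf:
    def test_no_mirna_means_no_hopf(self, with_params):
        """Without the miRNA loop there is no negative feedback to oscillate."""
        d = ms.sweep_alpha(with_params(gamma=0.0), GRID)
        assert d.hopf_points == []

    def test_hopf_pair_on_oscillatory_branch(self, with_params):
        p = with_params(gamma=1.6)
        d = ms.sweep_alpha(p, GRID)
        assert len(d.hopf_points) == 2
        for b in d.hopf_points:
            assert b.bracket_width <= 1e-8
            # the crossing happens on a complex-eigenvalue branch
            st = solve_steady_states(p, alpha=b.alpha_at + 1e-5)
            s = min(st, key=lambda s: abs(s.phi_star - b.phi_at))
            assert any(abs(e.imag) > 1e-6 for e in s.eigenvalues)

    def test_hopf_location_matches_dense_eigen_scan(self, with_params):
        p = with_params(gamma=1.6)
        d = ms.sweep_alpha(p, GRID)
        upper = [b for b in d.hopf_points if b.alpha_at > 0.2][0]
        dense = np.linspace(0.15, 0.3, 10_000)
        signs = []
        for a in dense:
            s = solve_steady_states(p, alpha=a)[-1]
            signs.append(max(e.real for e in s.eigenvalues) > 0)
        flips = dense[:-1][np.diff(np.asarray(signs, dtype=int)) != 0]
        assert len(flips) == 1
        assert upper.alpha_at == pytest.approx(flips[0], abs=1e-4)


class TestSwitchCharacter:
    def test_no_mirna_is_one_way(self, with_params):
        """Gamma = 0: the deactivating fold sits at negative stimulus."""
        assert ms.switch_character(with_params(gamma=0.0)) == "one_way_switch"

    def test_feedback_staging_with_kappa(self, with_params):
        """Increasing positive feedback stages monostable -> bistable -> one-way."""
        labels = [
            ms.switch_character(with_params(kappa=k)) for k in (2.5, 3.0, 4.0)
        ]
        assert labels == ["monostable", "bistable_switch", "one_way_switch"]

    def test_staging_is_monotone_along_kappa_scan(self, with_params):
        order = {"monostable": 0, "bistable_switch": 1, "one_way_switch": 2}
        seq = [
            order[ms.switch_character(with_params(kappa=k))]
            for k in np.linspace(2.0, 4.5, 11)
        ]
        assert seq == sorted(seq)

    def test_mirna_expands_reversible_window(self, with_params):
        """Gamma > 0 turns the one-way switch reversible inside the physical
        window: the bistable-switch stimulus interval grows from zero."""

        def reversible_length(p):
            d = ms.sweep_alpha(p, GRID)
            folds = sorted(b.alpha_at for b in d.saddle_nodes)
            if ms.switch_character(p) != "bistable_switch":
                return 0.0
            return folds[1] - folds[0]

        assert reversible_length(with_params(gamma=0.0)) == 0.0
        assert reversible_length(with_params(gamma=1.6)) > 0.02

    def test_agrees_with_hysteresis_simulation(self, with_params):
        """Character labels match what a slow triangular ramp actually does."""
        # reversible: both jumps observed
        p = with_params(gamma=1.6, epsilon=1.0, alpha=0.05)
        assert ms.switch_character(p) == "bistable_switch"
        h = ms.hysteresis_loop(p, alpha_lo=0.05, alpha_hi=0.2, ramp_rate=5e-5)
        assert h["jump_up_alpha"] is not None and h["jump_down_alpha"] is not None
        # one-way: jumps up, never returns within the physical window
        q = with_params(gamma=1.0, epsilon=1.0, alpha=0.0)
        assert ms.switch_character(q) == "one_way_switch"
        h = ms.hysteresis_loop(q, alpha_lo=0.0, alpha_hi=0.13, ramp_rate=5e-5)
        assert h["jump_up_alpha"] is not None
        assert h["jump_down_alpha"] is None


class TestPointwiseRegime:
    def test_no_feedback_is_always_monostable(self, with_params):
        for gamma, alpha, eps in [(0.0, 0.05, 0.02), (1.5, 0.2, 0.2)]:
            p = with_params(kappa=0.0, gamma=gamma, alpha=alpha, epsilon=eps)
            assert ms.pointwise_regime(p) == "monostable"

    def test_bistable_point(self, ref):
        assert ms.pointwise_regime(ref) == "bistable"

    def test_labels_agree_with_multistart_integration(self, rng, with_params):
        """Regime labels match attractor counting from scattered starts."""
        proto = lambda a: ms.StimulusProtocol(kind="constant", base_level=a)
        for _ in range(8):
            p = with_params(
                kappa=float(rng.uniform(2.2, 4.2)),
                gamma=float(rng.uniform(0.0, 1.8)),
                alpha=float(rng.uniform(0.01, 0.28)),
            )
            label = ms.pointwise_regime(p)
            finals = []
            oscillating = False
            for phi0, mu0 in [(0.0, 0.0), (0.5, 0.5), (1.5, 1.5), (3.0, 1.0),
                              (0.2, 2.5)]:
                traj = ms.integrate_rk4((phi0, mu0), p, proto(p.alpha),
                                        t_end=2500.0, dt=0.02, store_every=50)
                tail = traj.phi[traj.t > 2400.0]
                if np.ptp(tail) > 1e-3:
                    oscillating = True
                else:
                    finals.append(traj.phi[-1])
            n_attractors = len(set(np.round(finals, 3)))
            if label == "oscillatory":
                assert oscillating
            elif label == "bistable":
                assert n_attractors == 2
            elif label in ("monostable", "excitable"):
                assert n_attractors <= 1 or not oscillating


class TestPhaseDiagram:
    def test_switch_map_no_mirna_column(self, ref):
        """At Gamma = 0 the kappa-alpha plane has no excitable/oscillatory cells."""
        p = dataclasses.replace(ref, gamma=0.0)
        d = ms.phase_diagram(
            "kappa", "alpha", np.linspace(2.0, 4.5, 12),
            np.linspace(0.0, 0.3, 12), p, mode="regime",
        )
        found = set(d.labels.ravel())
        assert "oscillatory" not in found and "excitable" not in found

    def test_boundaries_separate_distinct_labels(self, ref):
        d = ms.phase_diagram(
            "kappa", "alpha", np.linspace(2.0, 4.5, 12),
            np.linspace(0.0, 0.3, 12), dataclasses.replace(ref, epsilon=1.0),
            mode="switch",
        )
        assert set(np.unique(d.labels)) >= {"monostable", "bistable_switch"}
        xg, yg = d.x_grid, d.y_grid
        for x, y in d.saddle_node_boundary:
            ix = int(np.argmin(np.abs(xg - x)))
            col = d.labels[:, ix]
            iy = int(np.searchsorted(yg, y)) - 1
            assert col[iy] != col[min(iy + 1, len(yg) - 1)]


class TestHysteresis:
    def test_monostable_traces_coincide(self, with_params):
        p = with_params(kappa=1.5, epsilon=1.0, alpha=0.05)
        h = ms.hysteresis_loop(p, alpha_lo=0.05, alpha_hi=0.2, ramp_rate=1e-4)
        assert h["jump_up_alpha"] is None and h["jump_down_alpha"] is None
        assert h["max_gap"] < 1e-3

    def test_jumps_bracket_the_folds(self, with_params):
        """Quasi-static jump locations sit within 2% of the fold alphas."""
        p = with_params(gamma=1.6, epsilon=1.0, alpha=0.05)
        d = ms.sweep_alpha(p, GRID)
        lo, hi = sorted(b.alpha_at for b in d.saddle_nodes)
        h = ms.hysteresis_loop(p, alpha_lo=0.05, alpha_hi=0.2)
        assert h["jump_up_alpha"] == pytest.approx(hi, rel=0.02)
        assert h["jump_down_alpha"] == pytest.approx(lo, rel=0.02)
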