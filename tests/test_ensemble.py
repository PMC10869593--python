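"""Ensemble model: heterogeneity, coupling schedule, integration,
observation."""

import numpy as np
import pytest
from dataclasses import replace

from phasegate.ensemble import (EnsembleParams, CouplingSchedule,
                                EnsembleState, sample_heterogeneity,
                                generate_coupling_schedule,
                                constant_schedule, coupling_at,
                                ensemble_deriv, rk4_step, observe,
                                initial_state, simulate, fixed_point,
                                is_self_sustained)


class TestHeterogeneity:
    def test_degenerate_uniform_interval(self):
        p = EnsembleParams(N=20, het_dist="uniform", het_low=0.7,
                           het_high=0.7)
        assert np.all(sample_heterogeneity(p) == 0.7)

    def test_uniform_mean_matches_law_of_large_numbers(self):
        p = EnsembleParams(N=10_000, het_dist="uniform", het_low=0.6,
                           het_high=0.8, seed=3)
        I = sample_heterogeneity(p)
        se = (0.8 - 0.6) / np.sqrt(12) / np.sqrt(p.N)
        assert abs(I.mean() - 0.7) < 3 * se

    def test_same_seed_gives_identical_draws(self):
        p = EnsembleParams(N=500, seed=11)
        assert np.array_equal(sample_heterogeneity(p),
                              sample_heterogeneity(p))

    def test_gaussian_draws_respect_truncation(self):
        p = EnsembleParams(N=5000, het_dist="gaussian", seed=5)
        I = sample_heterogeneity(p)
        assert I.min() >= p.het_low and I.max() <= p.het_high

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            EnsembleParams(het_low=0.8, het_high=0.6)

    def test_every_supported_current_is_self_sustained(self):
        p = EnsembleParams()
        for I in np.linspace(p.het_low, p.het_high, 25):
            assert is_self_sustained(I, p.c1, p.c2, p.c3)

    def test_subthreshold_current_is_excitable_not_oscillatory(self):
        # below I ~ 0.34 the fixed point is stable (trace < 0)
        assert not is_self_sustained(0.2)

    def test_fixed_point_solves_nullclines(self):
        xs, ys = fixed_point(0.6)
        assert abs(xs - xs ** 3 / 3 - ys + 0.6) < 1e-9
        assert abs(0.1 * (xs - 0.8 * ys + 0.7)) < 1e-9


class TestCouplingSchedule:
    def test_zero_width_distribution_gives_constant_levels(self):
        s = generate_coupling_schedule(0.025, 0.0, 200, 500, 5000, seed=1)
        assert np.all(s.levels == 0.025)

    def test_paper_parameters_bound_levels_and_durations(self):
        s = generate_coupling_schedule(0.025, 0.015, 200, 500, 3e4,
                                       seed=2)
        assert s.levels.min() >= 0.01 and s.levels.max() <= 0.04
        dur = np.diff(s.switch_times)
        assert dur.min() >= 200 and dur.max() <= 500
        assert s.horizon >= 3e4  # plateaus tile the horizon

    def test_mean_level_matches_uniform_moments(self):
        s = generate_coupling_schedule(0.025, 0.015, 1.0, 1.0001,
                                       10_000, seed=3)
        se = 2 * 0.015 / np.sqrt(12) / np.sqrt(s.levels.size)
        assert abs(s.levels.mean() - 0.025) < 3 * se

    def test_nonpositive_tau_min_rejected(self):
        with pytest.raises(ValueError):
            generate_coupling_schedule(0.025, 0.015, 0.0, 500, 1000)

    def test_lookup_is_left_closed_right_open(self):
        s = CouplingSchedule(np.array([0.0, 250.0, 600.0]),
                             np.array([0.02, 0.03]), 0.025, 0.005,
                             250.0, 350.0)
        assert coupling_at(s, 100.0) == 0.02
        assert coupling_at(s, 250.0) == 0.03  # boundary -> new plateau

    def test_lookup_beyond_horizon_raises(self):
        s = constant_schedule(0.02, 100.0)
        with pytest.raises(ValueError):
            coupling_at(s, 100.0)
        assert coupling_at(s, 50.0) == 0.02


class TestDerivative:
    def test_single_oscillator_at_origin(self):
        st = EnsembleState(0.0, np.zeros(1), np.zeros(1), np.zeros(1))
        dx, dy = ensemble_deriv(st, eps=0.0, P=0.0, psi=np.pi / 4)
        assert dx[0] == pytest.approx(0.0)
        assert dy[0] == pytest.approx(0.07)

    def test_stimulus_enters_along_psi(self):
        st = EnsembleState(0.0, np.zeros(3), np.zeros(3), np.zeros(3))
        dx0, dy0 = ensemble_deriv(st, 0.0, 0.0, np.pi / 4)
        dx1, dy1 = ensemble_deriv(st, 0.0, 1.0, np.pi / 4)
        inc = np.cos(np.pi / 4)
        assert np.allclose(dx1 - dx0, inc)
        assert np.allclose(dy1 - dy0, inc)  # sin(pi/4) == cos(pi/4)

    def test_identical_oscillators_stay_identical(self):
        st = EnsembleState(0.0, np.full(5, 1.3), np.full(5, -0.2),
                           np.full(5, 0.6))
        dx, dy = ensemble_deriv(st, 0.05, 0.7, 0.3)
        assert np.all(dx == dx[0]) and np.all(dy == dy[0])


class TestIntegration:
    def test_rk4_matches_fine_step_reference(self):
        p = EnsembleParams(N=10, seed=4)
        sched = constant_schedule(0.02, 200.0)
        st = initial_state(p, seed=9)
        coarse = st.copy()
        for _ in range(1000):  # 100 time units at dt = 0.1
            coarse = rk4_step(coarse, sched, None, p)
        fine = st.copy()
        p_fine = replace(p, dt=0.001)
        for _ in range(100_000):
            fine = rk4_step(fine, sched, None, p_fine)
        assert np.max(np.abs(coarse.x - fine.x)) < 1e-3

    def test_trajectory_independent_of_psi_without_stimulus(self):
        p1 = EnsembleParams(N=5, psi=0.0, seed=4)
        p2 = EnsembleParams(N=5, psi=2.1, seed=4)
        sched = constant_schedule(0.02, 100.0)
        s1 = initial_state(p1, seed=2)
        s2 = initial_state(p2, seed=2)
        for _ in range(200):
            s1 = rk4_step(s1, sched, None, p1)
            s2 = rk4_step(s2, sched, None, p2)
        assert np.array_equal(s1.x, s2.x)

    def test_single_unit_converges_to_closed_orbit(self):
        # Poincare return: successive upward crossings of x = 0 repeat
        p = EnsembleParams(N=1, het_dist="uniform", het_low=0.6,
                           het_high=0.6)
        sched = constant_schedule(0.0, 2000.0)
        st = EnsembleState(0.0, np.array([1.0]), np.array([0.0]),
                           np.array([0.6]))
        ys = []
        prev_x, prev_y = st.x[0], st.y[0]
        for _ in range(15_000):
            st = rk4_step(st, sched, None, p)
            if prev_x < 0.0 <= st.x[0] and st.t > 500:
                # interpolate y at the section crossing x = 0
                frac = -prev_x / (st.x[0] - prev_x)
                ys.append(prev_y + frac * (st.y[0] - prev_y))
            prev_x, prev_y = st.x[0], st.y[0]
        ys = np.array(ys)
        assert ys.size >= 10
        assert np.max(np.abs(ys - ys.mean())) < 1e-3

    def test_blowup_raises_with_diagnostic(self):
        p = EnsembleParams(N=2, dt=0.1)
        sched = constant_schedule(0.0, 10.0)
        st = EnsembleState(0.0, np.full(2, 1e154), np.zeros(2),
                           np.full(2, 0.6))
        with pytest.raises(FloatingPointError):
            rk4_step(st, sched, None, p)


class TestObservation:
    def test_zero_noise_observable_equals_mean_field(self, rng):
        st = EnsembleState(0.0, np.array([1.0, 2.0]), np.zeros(2),
                           np.full(2, 0.6))
        rec = observe(st, 0.0, rng)
        assert rec.X_N == rec.X == 1.5

    def test_noise_std_matches_sigma(self):
        st = EnsembleState(0.0, np.ones(2), np.zeros(2), np.full(2, 0.6))
        g = np.random.default_rng(0)
        devs = np.array([observe(st, 3.0, g).X_N - 1.0
                         for _ in range(100_000)])
        assert abs(devs.std() - 3.0) / 3.0 < 0.02

    def test_simulate_is_bit_reproducible(self):
        p = EnsembleParams(N=20, seed=1)
        sched = generate_coupling_schedule(0.025, 0.015, 200, 500,
                                           1000, seed=5)
        t1, s1 = simulate(p, sched, 300.0, noise_seed=8, ic_seed=9)
        t2, s2 = simulate(p, sched, 300.0, noise_seed=8, ic_seed=9)
        assert np.array_equal(t1["X_N"].to_numpy(),
                              t2["X_N"].to_numpy())
        assert np.array_equal(s1.x, s2.x)
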