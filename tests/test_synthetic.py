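"""Simulator contracts: fixed points, independent-integrator oracles, seed
determinism, clipping, equilibria and the noise scaling of Euler-Maruyama."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from floquet_ews import (
    Constant,
    KlausmeierParams,
    LinearRamp,
    LogisticParams,
    PiecewiseNoiseParams,
    PitchforkParams,
    SigmoidRamp,
    VegetationRDParams,
    simulate_klausmeier,
    simulate_logistic,
    simulate_piecewise_noise,
    simulate_pitchfork,
    simulate_vegetation_rd,
)
from floquet_ews.synthetic import klausmeier_equilibrium


class TestPitchfork:
    def test_fixed_point_at_origin(self):
        run = simulate_pitchfork(PitchforkParams(
            p_schedule=Constant(-1.0), A=0.0, sigma=0.0, x0=0.0, duration=2.0))
        assert np.all(run.output.values == 0.0)

    def test_matches_independent_euler_integration(self):
        # second, independently written integrator of the same drift
        params = PitchforkParams(p_schedule=LinearRamp(-2.0, 1.0, 1.0, 4.0),
                                 A=0.5, sigma=0.0, x0=0.3, duration=4.0)
        run = simulate_pitchfork(params)
        dt = params.dt
        x = params.x0
        expected = []
        t = 0.0
        for _ in range(len(run.output)):
            p_t = -2.0 if t <= 1.0 else min(-2.0 + 3.0 * (t - 1.0) / 3.0, 1.0)
            x = x + (p_t * x - x ** 3 + 0.5 * math.cos(params.omega * t)) * dt
            t += dt
            expected.append(x)
        np.testing.assert_allclose(run.output.values, expected, rtol=1e-12)

    def test_seed_determinism(self):
        a = simulate_pitchfork(PitchforkParams(sigma=0.1, duration=3.0, seed=42))
        b = simulate_pitchfork(PitchforkParams(sigma=0.1, duration=3.0, seed=42))
        assert np.array_equal(a.output.values, b.output.values)

    def test_saved_length_contract(self):
        params = PitchforkParams(duration=2.0, save_stride=5)
        run = simulate_pitchfork(params)
        assert len(run.output) == math.floor(params.duration / (params.dt * 5))

    def test_noise_scaling_stationary_variance(self):
        """Halving dt leaves the small-fluctuation stationary variance
        unchanged (correct sqrt(dt) Euler-Maruyama noise scaling)."""
        variances = []
        for dt, stride in [(1 / 365, 1), (1 / 730, 2)]:
            vs = []
            for seed in range(8):
                run = simulate_pitchfork(PitchforkParams(
                    p_schedule=Constant(-2.0), A=0.0, sigma=0.1,
                    dt=dt, save_stride=stride, duration=40.0, seed=seed))
                vs.append(np.var(run.output.values[365:]))
            variances.append(np.mean(vs))
        assert variances[0] == pytest.approx(variances[1], rel=0.1)

    def test_transition_marker_in_final_ramp_phase(self):
        run = simulate_pitchfork(PitchforkParams(seed=3))
        assert run.transition_time is not None
        assert 20.0 < run.transition_time < 30.0


class TestLogistic:
    def test_absorbing_state(self):
        run = simulate_logistic(LogisticParams(x0=0.0, A=0.0, sigma=0.0, duration=2.0))
        assert np.all(run.output.values == 0.0)

    def test_carrying_capacity_fixed_point(self):
        run = simulate_logistic(LogisticParams(
            r_schedule=Constant(1.0), A=0.0, sigma=0.0, x0=0.01, duration=40.0))
        assert abs(run.output.values[-1] - 1.0) < 1e-6

    def test_clipping_contract(self):
        run = simulate_logistic(LogisticParams(sigma=2.0, duration=3.0, seed=1))
        assert run.output.values.min() >= 0.0


class TestPiecewiseNoise:
    def test_homogeneous_segments_have_similar_variance(self):
        params = PiecewiseNoiseParams(
            segments=[(0.0, 1500.0, 0.0), (1500.0, 3000.0, 0.0)], seed=0)
        run = simulate_piecewise_noise(params)
        t, v = run.output.times, run.output.values
        season = params.season_amplitude * np.sin(2 * np.pi * t / params.season_period)
        resid = v - season
        v1 = np.var(resid[t <= 1500])
        v2 = np.var(resid[t > 1500])
        assert 0.8 < v1 / v2 < 1.25

    def test_white_noise_binning_independence(self):
        params = PiecewiseNoiseParams(
            base_process=0.0, season_amplitude=0.0,
            segments=[(0.0, 3000.0, 0.0)], seed=1)
        v = simulate_piecewise_noise(params).output.values
        ac1 = np.corrcoef(v[:-1], v[1:])[0, 1]
        assert abs(ac1) < 3.0 / np.sqrt(v.size)

    def test_variance_ratio_matches_closed_form(self):
        """Two segments with extra SDs (0, s): residual variance ratio approx
        (sigma^2 + s^2)/sigma^2 at the substep level."""
        s_extra = 2.0
        ratios = []
        for seed in range(6):
            params = PiecewiseNoiseParams(
                base_process=0.0, season_amplitude=0.0, sigma=1.0,
                segments=[(0.0, 2000.0, 0.0), (2000.0, 4000.0, s_extra)],
                seed=seed)
            run = simulate_piecewise_noise(params)
            t, v = run.output.times, run.output.values
            ratios.append(np.var(v[t > 2000]) / np.var(v[t <= 2000]))
        expected = 1.0 + s_extra ** 2
        assert np.mean(ratios) == pytest.approx(expected, rel=0.15)

    def test_empty_segments_rejected(self):
        with pytest.raises(ValueError):
            PiecewiseNoiseParams(segments=[]).validate()


class TestVegetationRD:
    def test_symmetry_preservation(self):
        run = simulate_vegetation_rd(VegetationRDParams(
            grid=(8, 8), sigma=0.0, A_rv_field=0.0, phase_field=0.0,
            E0_schedule=Constant(0.8), A_E0=0.1, duration=200.0, spinup=20.0))
        data = run.output.data
        assert np.all(data == data[:1, :])  # all cells bitwise identical

    def test_converges_to_root_finder_equilibrium(self):
        """sigma=0, constant stress: the uniform steady state matches an
        independent 1D root-finder coupling growth and stress feedback."""
        E0, h_v, p_exp = 1.5, 0.5, 6.0
        run = simulate_vegetation_rd(VegetationRDParams(
            grid=(4, 4), sigma=0.0, A_rv_field=0.0, phase_field=0.0,
            E0_schedule=Constant(E0), A_E0=0.0, h_v=h_v, p_exp=p_exp,
            duration=2000.0, spinup=50.0))
        v_end = float(run.output.data[:, -1].mean())

        def g(V):
            E = E0 * h_v / (h_v + V)
            return V * (1.0 + E ** p_exp) - 1.0

        v_star = brentq(g, 0.5, 1.2)
        assert v_end == pytest.approx(v_star, abs=1e-4)

    def test_seed_determinism(self):
        kw = dict(grid=(6, 6), duration=60.0, spinup=10.0, seed=9)
        a = simulate_vegetation_rd(VegetationRDParams(**kw))
        b = simulate_vegetation_rd(VegetationRDParams(**kw))
        assert np.array_equal(a.output.data, b.output.data)


class TestKlausmeier:
    def test_uniform_equilibrium_matches_algebraic_solve(self):
        a, m = 2.5, 0.45
        n_star, w_star = klausmeier_equilibrium(a, m)
        # oracle: the equilibrium equations themselves
        assert w_star * n_star ** 2 == pytest.approx(m * n_star, rel=1e-12)
        assert a == pytest.approx(w_star + w_star * n_star ** 2, rel=1e-12)
        run = simulate_klausmeier(KlausmeierParams(
            grid=(4, 4), sigma=0.0, A_season=0.0, a_schedule=Constant(a),
            duration=60.0, spinup=5.0))
        assert run.output.data[:, -1].mean() == pytest.approx(n_star, rel=1e-6)

    def test_collapse_below_rainfall_threshold(self):
        # a < 2m: the equilibrium quadratic has negative discriminant
        a, m = 0.5, 0.45
        assert a * a - 4 * m * m < 0
        assert klausmeier_equilibrium(a, m) is None
        run = simulate_klausmeier(KlausmeierParams(
            grid=(4, 4), sigma=0.0, A_season=0.0, a_schedule=Constant(a),
            duration=120.0, spinup=5.0))
        start = run.output.data[:, 0].mean()
        assert run.output.data[:, -1].mean() < 1e-3 * start

    def test_spatial_symmetry_without_noise(self):
        run = simulate_klausmeier(KlausmeierParams(
            grid=(4, 4), sigma=0.0, A_season=0.3, a_schedule=Constant(2.5),
            duration=30.0, spinup=5.0))
        data = run.output.data
        assert np.all(data == data[:1, :])


class TestSchedules:
    def test_linear_ramp_holds_and_interpolates(self):
        r = LinearRamp(-1.0, 1.0, 10.0, 20.0)
        np.testing.assert_allclose(r([0.0, 10.0, 15.0, 20.0, 99.0]),
                                   [-1.0, -1.0, 0.0, 1.0, 1.0])

    def test_sigmoid_ramp_midpoint_and_limits(self):
        r = SigmoidRamp(2.0, 0.0, 50.0, 0.5)
        assert float(r(50.0)) == pytest.approx(1.0)
        assert float(r(-100.0)) == pytest.approx(2.0, abs=1e-6)
        assert r.t_start < 50.0
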