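"""Recursive least squares with forgetting, Fisher dynamics, two-stage loop."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import wardflow as wf
from wardflow.estimator import EstimatorState


class TestResidualSignal:
    def test_zero_when_equal(self):
        y = wf.residual_signal([1.0, 2.0], [1.0, 2.0])
        np.testing.assert_array_equal(y, 0.0)

    def test_constructed_perturbation_recovered_exactly(self):
        psi_col = np.array([0.3, -0.7])
        y = wf.residual_signal(np.array([1.0, 2.0]) + 0.05 * psi_col, [1.0, 2.0])
        np.testing.assert_allclose(y, 0.05 * psi_col, atol=1e-15)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            wf.residual_signal([1.0], [1.0, 2.0])

    def test_first_order_in_dk(self, tandem_net, tandem_rates, square_wave_input):
        """Noise-free state at kbar + dk minus model at kbar is Psi dk + O(|dk|^2)."""
        u = square_wave_input
        times = np.arange(0.0, 121.0)
        dyn = wf.build_system_matrices(tandem_net, tandem_rates)
        base = wf.integrate_state(dyn, np.zeros(2), u, times)
        sens = wf.integrate_sensitivities(tandem_net, tandem_rates, base, u)
        errs = []
        for scale in (0.02, 0.01):
            dk = scale * tandem_rates.values
            pert = wf.integrate_state(
                wf.build_system_matrices(
                    tandem_net, tandem_rates.with_values(tandem_rates.values + dk)
                ),
                np.zeros(2),
                u,
                times,
            )
            y = pert.states - base.states
            linear = np.einsum("tnr,r->tn", sens.psi, dk)
            errs.append(np.max(np.abs(y - linear)))
        # halving |dk| must shrink the residual error ~4x (second order)
        assert errs[1] < errs[0] / 3


class TestRlsStep:
    def test_no_information_grows_gain(self):
        es = EstimatorState.initial(2, a=0.5, p0=10.0)
        out = wf.rls_step(es, np.zeros((3, 2)), np.zeros(3), dt=0.1)
        np.testing.assert_array_equal(out.dk_hat, 0.0)
        np.testing.assert_allclose(out.P, 10.0 * np.exp(0.5 * 0.1) * np.eye(2), rtol=1e-12)

    def test_scalar_consistency(self):
        """Constant regressor/target: the estimate converges to the target value."""
        es = EstimatorState.initial(1, a=0.0, p0=100.0)
        for _ in range(2000):
            es = wf.rls_step(es, [[1.0]], [3.7], dt=0.05)
        assert es.dk_hat[0] == pytest.approx(3.7, abs=1e-3)

    def test_matches_ode_oracle(self):
        """Discrete recursion vs fine-tolerance ODE integration of the RLS dynamics."""
        a, p0, T, dt = 0.3, 100.0, 10.0, 0.01

        def psi_f(t):
            return np.sin(0.7 * t) + 1.2

        def y_f(t):
            return 0.8 * psi_f(t) + 0.1 * np.cos(t)

        es = EstimatorState.initial(1, a, p0)
        for i in range(int(T / dt)):
            t1 = (i + 1) * dt
            es = wf.rls_step(es, [[psi_f(t1)]], [y_f(t1)], dt)

        def ode(t, z):
            dk, P = z
            ps = psi_f(t)
            e = y_f(t) - ps * dk
            return [P * ps * e, a * P - P * ps * ps * P]

        sol = solve_ivp(ode, [0, T], [0.0, p0], rtol=1e-10, atol=1e-12)
        assert abs(es.dk_hat[0] - sol.y[0, -1]) < 1e-4
        assert abs(es.P[0, 0] - sol.y[1, -1]) < 1e-4

    def test_invalid_dt(self):
        es = EstimatorState.initial(1, 0.1)
        with pytest.raises(ValueError, match="dt"):
            wf.rls_step(es, [[1.0]], [0.0], dt=0.0)


class TestFisherStep:
    def test_closed_form_saturation(self):
        """Constant unit regressor with a = 1: R(t) = 1 - exp(-t)."""
        es = EstimatorState.initial(1, a=1.0, p0=1e6)
        es = EstimatorState(0.0, es.dk_hat, es.P, np.zeros((1, 1)), 1.0)
        dt = 1e-3
        # regressor active from t=0: seed the previous-regressor slot
        es = wf.fisher_step(es, [[1.0]], dt)
        for _ in range(int(1.0 / dt) - 1):
            es = wf.fisher_step(es, [[1.0]], dt)
        assert es.fisher[0, 0] == pytest.approx(1 - np.exp(-1.0), abs=2e-3)

    def test_pure_accumulation(self):
        """a = 0, unit regressor: R(t) = t (up to the first half step)."""
        es = EstimatorState(0.0, np.zeros(1), np.eye(1), np.zeros((1, 1)), 0.0)
        dt = 0.01
        for _ in range(100):
            es = wf.fisher_step(es, [[1.0]], dt)
        assert es.fisher[0, 0] == pytest.approx(1.0, abs=dt)

    def test_matches_quadrature_oracle(self):
        """Trapezoidal Fisher stepping vs adaptive quadrature of the defining integral."""
        a, T, dt = 0.4, 2.0, 5e-4

        def psi_f(t):
            return np.array([[np.sin(0.9 * t) + 0.5, np.cos(0.3 * t)]])

        # regressor is active from t = 0: seed the previous-regressor slot
        es = EstimatorState(
            0.0, np.zeros(2), np.eye(2), np.zeros((2, 2)), a,
            _psi_prev_fisher=psi_f(0.0),
        )
        n = int(round(T / dt))
        for i in range(n):
            es = wf.fisher_step(es, psi_f((i + 1) * dt), dt)
        for r in range(2):
            for c in range(2):
                ref = quad(
                    lambda s: np.exp(-a * (T - s))
                    * (psi_f(s)[0, r] * psi_f(s)[0, c]),
                    0,
                    T,
                    limit=400,
                    epsabs=1e-12,
                )[0]
                assert abs(es.fisher[r, c] - ref) < 1e-6


class TestDualityAndForgetting:
    def test_gain_fisher_duality_along_trajectory(self):
        """With matched initialization P(0)^-1 = eps I = R(0), P R = I throughout."""
        eps = 1e-3
        es = EstimatorState(0.0, np.zeros(2), (1 / eps) * np.eye(2), eps * np.eye(2), a=0.2)
        rng = np.random.default_rng(4)
        for i in range(300):
            psi = rng.normal(size=(2, 2))
            y = rng.normal(size=2)
            es = wf.rls_step(es, psi, y, dt=0.05)
            es = wf.fisher_step(es, psi, dt=0.05)
            assert np.max(np.abs(es.P @ es.fisher - np.eye(2))) < 1e-6

    def test_forgetting_bounds_information(self):
        """a > 0 with persistent excitation keeps R bounded; a = 0 accumulates."""
        rng = np.random.default_rng(9)
        psis = [rng.normal(size=(2, 2)) for _ in range(2000)]
        for a, bounded in ((0.5, True), (0.0, False)):
            es = EstimatorState(0.0, np.zeros(2), np.eye(2), np.zeros((2, 2)), a)
            traces = []
            for psi in psis:
                es = wf.fisher_step(es, psi, dt=0.1)
                traces.append(np.trace(es.fisher))
            traces = np.array(traces)
            if bounded:
                assert traces.max() < 50  # saturates near increment/(1 - lambda)
            else:
                assert np.all(np.diff(traces) >= -1e-12)
                assert traces[-1] > 100  # keeps accumulating


def _simulate_tandem(net, kbar, k_factor, u, times, noise_q, noise_r, seed):
    ktrue = kbar.with_values(k_factor * kbar.values)
    om = wf.ObservationModel(np.eye(2), max(noise_r, 1e-6) * np.eye(2))
    dyn = wf.build_system_matrices(net, ktrue, Q=noise_q * np.eye(2))
    if noise_q == 0 and noise_r == 0:
        traj = wf.integrate_state(dyn, np.zeros(2), u, times)
        return wf.ObservationSeries(times, traj.states), om
    _, series = wf.simulate_linear_sde(dyn, np.zeros(2), u, times, om, seed=seed)
    return series, om


class TestTwoStage:
    times = np.arange(0.0, 481.0, 1.0)

    def test_null_perturbation_noise_free(self, tandem_net, tandem_rates, square_wave_input):
        """Data generated exactly at kbar with no noise: dk_hat stays at zero."""
        series, _ = _simulate_tandem(
            tandem_net, tandem_rates, 1.0, square_wave_input, self.times, 0.0, 0.0, 0
        )
        om = wf.ObservationModel(np.eye(2), 1e-6 * np.eye(2))
        res = wf.two_stage_estimate(
            tandem_net,
            tandem_rates,
            series,
            om,
            wf.EstimatorConfig(a=0.01, burn_in_epochs=60),
            u=square_wave_input,
            process_noise=1e-4,
        )
        assert np.linalg.norm(res.dk_hat[-1]) < 1e-6

    def test_recovers_ten_percent_perturbation(
        self, tandem_net, tandem_rates, square_wave_input
    ):
        """True rates 1.10 kbar, low noise, 480 one-minute epochs: each rate within 5%."""
        series, om = _simulate_tandem(
            tandem_net, tandem_rates, 1.10, square_wave_input, self.times,
            1e-4, 0.05**2, 42,
        )
        res = wf.two_stage_estimate(
            tandem_net,
            tandem_rates,
            series,
            om,
            wf.EstimatorConfig(a=0.01, burn_in_epochs=60),
            u=square_wave_input,
            process_noise=1e-4,
        )
        ktrue = 1.10 * tandem_rates.values
        rel = np.abs(res.k_final - ktrue) / ktrue
        assert np.all(rel < 0.05)
        assert res.identifiable

    def test_more_observation_noise_does_not_shrink_gain(
        self, tandem_net, tandem_rates, square_wave_input
    ):
        """Doubling R_obs leaves the terminal trace of P no smaller (seeded pair)."""
        traces = []
        for r_obs in (0.05**2, 4 * 0.05**2):
            series, om = _simulate_tandem(
                tandem_net, tandem_rates, 1.10, square_wave_input, self.times,
                1e-4, r_obs, 42,
            )
            res = wf.two_stage_estimate(
                tandem_net, tandem_rates, series, om,
                wf.EstimatorConfig(a=0.01, burn_in_epochs=60),
                u=square_wave_input, process_noise=1e-4,
            )
            traces.append(np.trace(res.estimator_state.P))
        assert traces[1] >= traces[0] * (1 - 1e-6)

    def test_permutation_equivariance(self, square_wave_input):
        """Relabelling/reordering species leaves the rate estimates unchanged.

        Noise-free data so both labelings see the identical physical path
        (state noise is drawn in state coordinates and would not permute).
        """
        text_a = "0 -> WAIT @ k0 [u]\nWAIT -> TRANSIT @ k1\nTRANSIT -> 0 @ k2\n"
        text_b = "TRANSIT -> 0 @ k2\n0 -> WAIT @ k0 [u]\nWAIT -> TRANSIT @ k1\n"
        results = []
        for text in (text_a, text_b):
            net = wf.parse_rule_file(text)
            kbar = wf.RateParameters.from_dict(net, {"k0": 1.0, "k1": 0.2, "k2": 0.1})
            ktrue = kbar.with_values(1.1 * kbar.values)
            H = np.eye(2)[[net.species_index("WAIT"), net.species_index("TRANSIT")]]
            om = wf.ObservationModel(H, 1e-6 * np.eye(2))
            dyn = wf.build_system_matrices(net, ktrue)
            traj = wf.integrate_state(dyn, np.zeros(2), square_wave_input, self.times)
            series = wf.ObservationSeries(self.times, traj.states @ H.T)
            res = wf.two_stage_estimate(
                net, kbar, series, om,
                wf.EstimatorConfig(a=0.01, burn_in_epochs=60),
                u=square_wave_input, process_noise=1e-4,
            )
            results.append(dict(zip(net.rate_names, res.k_final)))
        for name in ("k0", "k1", "k2"):
            assert results[0][name] == pytest.approx(results[1][name], rel=1e-6)

    def test_sklearn_estimator_interface(self, tandem_net, tandem_rates, square_wave_input):
        series, om = _simulate_tandem(
            tandem_net, tandem_rates, 1.10, square_wave_input, self.times,
            1e-4, 0.05**2, 42,
        )
        est = wf.TwoStageRateEstimator(
            network=tandem_net, k_nominal=tandem_rates, observation_model=om,
            u=square_wave_input, a=0.01, burn_in_epochs=60, process_noise=1e-4,
        ).fit(series)
        assert est.k_hat_.shape == (3,)
        assert est.P_.shape == (3, 3)
        assert est.get_params()["a"] == 0.01
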