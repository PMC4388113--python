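"""Closed-form Ornstein-Uhlenbeck fluctuation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm, solve_lyapunov

import wcfield as wc
from wcfield.model import find_steady_states
from wcfield.ou import (
    NoiseModel,
    dft_wavenumbers,
    drift_matrix,
    finite_record_expectation,
    predict,
    spatial_spectrum,
    spatial_variance_and_acf,
    temporal_acf,
    temporal_correlation,
    white_noise_reference_variance,
)


@pytest.fixture(scope="module")
def stable_setting(homogeneous):
    p = homogeneous.replace(P=2.3)
    return p, find_steady_states(p)[-1]


class TestDriftMatrix:
    def test_is_negated_jacobian(self, stable_setting):
        p, ss = stable_setting
        for q in (0.0, 0.01, 0.1):
            np.testing.assert_allclose(
                drift_matrix(p, ss, q), -wc.jacobian_q(p, ss, q)
            )

    def test_large_q_limit(self, stable_setting):
        p, ss = stable_setting
        np.testing.assert_allclose(
            drift_matrix(p, ss, 1e5),
            np.diag([1.0 / p.tau_E, 1.0 / p.tau_I]),
            atol=1e-10,
        )

    def test_rejects_unstable_mode(self, space):
        # supercritical Turing setting: the critical mode has alpha > 0
        p = space.replace(P=2.34, sigma_EI=200.0, sigma_IE=200.0)
        ss = find_steady_states(p)[-1]
        curve = wc.dispersion(p, ss, wc.default_q_grid())
        q_star = curve.q_grid[int(np.argmax(curve.alpha))]
        with pytest.raises(ValueError, match="not stable"):
            drift_matrix(p, ss, float(q_star))

    def test_near_singular_at_turing_threshold(self, space):
        # approaching the threshold from below, det A(q*) -> 0
        p = space.replace(P=2.34, sigma_EI=137.0, sigma_IE=137.0)
        ss = find_steady_states(p)[-1]
        curve = wc.dispersion(p, ss, wc.default_q_grid())
        i = int(np.argmax(curve.alpha))
        assert -1e-3 < curve.alpha[i] < 0
        A = drift_matrix(p, ss, float(curve.q_grid[i]))
        assert abs(np.linalg.det(A)) < 2e-4


class TestSpatialSpectrum:
    def test_decoupled_closed_form(self):
        A = np.diag([0.25, 2.0])
        D = np.diag([3.0, 5.0])
        np.testing.assert_allclose(
            spatial_spectrum(A, D), np.diag([3.0 / (2 * 0.25), 5.0 / (2 * 2.0)])
        )

    def test_linearity_in_diffusion(self, stable_setting):
        p, ss = stable_setting
        A = drift_matrix(p, ss, 0.005)
        D = NoiseModel(2e-4, 1e-4).diffusion_matrix(p)
        np.testing.assert_allclose(
            spatial_spectrum(A, 2 * D), 2 * spatial_spectrum(A, D)
        )

    def test_rejects_unstable_drift(self):
        with pytest.raises(ValueError, match="not stable"):
            spatial_spectrum(np.diag([-1.0, 2.0]), np.eye(2))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a11=st.floats(0.05, 5.0),
        a22=st.floats(0.05, 5.0),
        a12=st.floats(-2.0, 2.0),
        a21=st.floats(-2.0, 2.0),
        d1=st.floats(0.01, 10.0),
        d2=st.floats(0.01, 10.0),
    )
    def test_solves_lyapunov_equation(self, a11, a22, a12, a21, d1, d2):
        A = np.array([[a11, a12], [a21, a22]])
        if np.trace(A) <= 1e-6 or np.linalg.det(A) <= 1e-6:
            return  # not a stable drift; precondition of the formula
        D = np.diag([d1, d2])
        G = spatial_spectrum(A, D)
        assert np.abs(A @ G + G @ A.T - D).max() < 1e-10 * max(d1, d2)
        assert G[0, 1] == pytest.approx(G[1, 0])
        assert np.all(np.linalg.eigvalsh((G + G.T) / 2) > -1e-12)

    def test_lyapunov_residual_on_model_grid(self, stable_setting):
        p, ss = stable_setting
        D = NoiseModel().diffusion_matrix(p)
        q, _ = dft_wavenumbers(3000.0, 200)
        for qi in q[::20]:
            A = drift_matrix(p, ss, float(qi))
            G = spatial_spectrum(A, D)
            assert np.abs(A @ G + G @ A.T - D).max() < 1e-12
            np.testing.assert_allclose(G, solve_lyapunov(A, D), atol=1e-14)


class TestTemporalCorrelation:
    def test_zero_lag_returns_spectrum(self, stable_setting):
        p, ss = stable_setting
        A = drift_matrix(p, ss, 0.0)
        G = spatial_spectrum(A, NoiseModel().diffusion_matrix(p))
        np.testing.assert_allclose(temporal_correlation(A, G, 0.0), G)

    def test_scalar_case_pure_exponential(self):
        a, g = 0.7, 2.5
        A, G = np.diag([a, 1.0]), np.diag([g, 1.0])
        for tau in (0.5, 2.0, 7.0):
            assert temporal_correlation(A, G, tau)[0, 0] == pytest.approx(
                g * np.exp(-a * tau)
            )

    def test_negative_lag_symmetry(self, stable_setting):
        p, ss = stable_setting
        A = drift_matrix(p, ss, 0.003)
        G = spatial_spectrum(A, NoiseModel().diffusion_matrix(p))
        np.testing.assert_allclose(
            temporal_correlation(A, G, -3.0), temporal_correlation(A, G, 3.0).T
        )

    def test_tail_decays_at_slowest_drift_rate(self, stable_setting):
        p, ss = stable_setting
        A = drift_matrix(p, ss, 0.05)   # large q: real, well-separated rates
        G = spatial_spectrum(A, NoiseModel().diffusion_matrix(p))
        slow = min(np.linalg.eigvals(A).real)
        t1, t2 = 200.0, 260.0
        T1 = temporal_correlation(A, G, t1)[0, 0]
        T2 = temporal_correlation(A, G, t2)[0, 0]
        assert -np.log(T2 / T1) / (t2 - t1) == pytest.approx(slow, rel=1e-3)

    def test_matrix_exponential_matches_series_oracle(self, stable_setting):
        p, ss = stable_setting
        A = drift_matrix(p, ss, 0.002)
        tau = 4.0
        M = np.eye(2)
        S = np.eye(2)
        for k in range(1, 60):
            M = M @ (-A * tau) / k
            S = S + M
        np.testing.assert_allclose(expm(-A * tau), S, atol=1e-14)


class TestTemporalAcf:
    def test_zero_lag_equals_point_variance(self, stable_setting):
        p, ss = stable_setting
        nm = NoiseModel()
        pred = predict(p, ss, nm, 999.0, 666, np.array([0.0, 1.0]))
        assert pred.C[0] == pytest.approx(pred.spatial_variance, rel=1e-12)

    def test_quadrature_convergence_in_mode_density(self, stable_setting):
        # halving the mode spacing (doubling L at fixed dx) changes C(tau)
        # by < 0.5% of the zero-lag value
        p, ss = stable_setting
        nm = NoiseModel()
        tau = np.array([0.0, 5.0, 20.0, 60.0])
        C1 = temporal_acf(p, ss, nm, 3000.0, 2000, tau)
        C2 = temporal_acf(p, ss, nm, 6000.0, 4000, tau)
        assert np.abs(C1 - C2).max() < 5e-3 * C1[0]

    def test_correlation_time_grows_toward_saddle_node(self, homogeneous):
        # slow decay-rate decreases monotonically as P -> P_SN on the bottom branch
        from wcfield.analysis import envelope, fit_biexponential

        tau = np.arange(0.0, 300.0001, 0.5)
        m2s, variances = [], []
        for P in (1.70, 1.75, 1.78):
            p = homogeneous.replace(P=P)
            ss = find_steady_states(p)[0]
            C = temporal_acf(p, ss, NoiseModel(), 3000.0, 2000, tau)
            fit = fit_biexponential(tau, envelope(C, tau))
            m2s.append(fit.m2)
            variances.append(fit.variance)
        assert m2s[0] > m2s[1] > m2s[2] > 0
        assert variances[0] < variances[1] < variances[2]

    def test_unstable_mode_listed_in_error(self, space):
        p = space.replace(P=2.34, sigma_EI=200.0, sigma_IE=200.0)
        ss = find_steady_states(p)[-1]
        with pytest.raises(ValueError, match="unstable"):
            temporal_acf(p, ss, NoiseModel(), 6000.0, 4000, np.array([0.0]))

    def test_hopf_side_lobe_period_matches_dispersion(self, hopf_params, hopf_steady_state):
        from wcfield.analysis import lobe_period

        tau = np.arange(0.0, 100.0001, 0.1)
        C = temporal_acf(hopf_params, hopf_steady_state, NoiseModel(), 999.0, 666, tau)
        omega0 = abs(hopf_steady_state.eigenvalues[0].imag)
        # lobes of the dominant oscillation ride on the monotone background;
        # strip it with the envelope fit before reading the lobe spacing
        from wcfield.analysis import fit_biexponential

        resid = C - fit_biexponential(tau, C)(tau)
        pk = [i for i in range(1, len(resid) - 1) if resid[i] >= resid[i - 1] and resid[i] >= resid[i + 1]]
        spacing = np.diff(tau[pk]).mean()
        assert spacing == pytest.approx(2 * np.pi / omega0, rel=0.05)


class TestSpatialStatistics:
    def test_acf_zero_lag_equals_variance_and_even(self, stable_setting):
        p, ss = stable_setting
        pred = predict(p, ss, NoiseModel(), 999.0, 666, np.array([0.0]))
        var, x, acf = spatial_variance_and_acf(pred)
        assert var == pytest.approx(pred.spatial_variance, rel=1e-12)
        i0 = int(np.argmin(np.abs(x)))
        assert acf[i0] == pytest.approx(var)
        # even in offset: compare x and -x entries away from the ends
        for k in range(1, 200, 37):
            assert acf[i0 + k] == pytest.approx(acf[i0 - k], abs=1e-10 * var + 1e-25)

    def test_turing_approach_grows_spectrum_peak(self, space):
        peaks = []
        for s in (125.0, 130.0, 135.0):
            p = space.replace(P=2.34, sigma_EI=s, sigma_IE=s)
            ss = find_steady_states(p)[-1]
            pred = predict(p, ss, NoiseModel(), 6000.0, 4000, np.array([0.0]))
            interior = pred.G11[3:]
            peaks.append(interior.max())
            # a genuine interior maximum away from q = 0
            assert int(np.argmax(pred.G11)) > 3
        assert peaks[0] < peaks[1] < peaks[2]

    def test_white_noise_reference_scaling(self, homogeneous):
        nm = NoiseModel(2e-4, 2e-4)
        v1 = white_noise_reference_variance(homogeneous, nm, 1.5)
        v2 = white_noise_reference_variance(homogeneous, nm, 3.0)
        assert v1 == pytest.approx(2 * v2)


class TestFiniteRecordExpectation:
    def test_reduces_to_identity_for_short_correlation(self):
        # exponentially decaying ACF with tau_corr << T: correction negligible
        lags = np.arange(0.0, 1000.001, 0.5)
        C = np.exp(-lags / 2.0)
        out = finite_record_expectation(C, lags, 1000.0, lags[:100])
        np.testing.assert_allclose(out, C[:100], atol=5e-3)

    def test_removes_mean_level_for_slow_component(self):
        lags = np.arange(0.0, 1000.001, 0.5)
        C = np.ones_like(lags)  # infinitely slow component
        out = finite_record_expectation(C, lags, 1000.0, lags[:10])
        # a constant component is entirely absorbed by mean subtraction
        np.testing.assert_allclose(out, 0.0, atol=1e-3)
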