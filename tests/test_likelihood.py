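"""Unit tests for the period fits and the integrated likelihood."""

import numpy as np
import pytest

import vowelbayes as vb
from vowelbayes.likelihood import IntegratedLikelihoodEvaluator, log_order_constant

from conftest import male_vowel_spec, periods_from_vowel
from oracles import exact_log_integrated_likelihood, sigma_marginal_argmax


def tiny_instance(seed, n=1, N=16, P=1, Q=1, sigma=0.05):
    """A small random dataset plus its design matrix at a random theta."""
    rng = np.random.default_rng(seed)
    B = rng.uniform(30, 120, Q)
    F = np.sort(rng.uniform(400, 1500, Q))
    th = vb.hz_to_internal(B, F, 8000.0)
    orders = vb.ModelOrders(P=P, Q=Q)
    Gs, ds = [], []
    for _ in range(n):
        G = vb.build_design_matrix(N, orders, th).values
        c = rng.uniform(-1.5, 1.5, orders.m)
        ds.append(G @ c + sigma * rng.standard_normal(N))
        Gs.append(G)
    ps = vb.PitchPeriodSet(periods=ds, fs=8000.0, norm_scale=1.0)
    return ps, orders, th, Gs


class TestFitPeriod:
    def test_zero_data(self):
        th = vb.hz_to_internal([54.0], [430.0], 8000.0)
        G = vb.build_design_matrix(40, vb.ModelOrders(P=2, Q=1), th)
        fit = vb.fit_period(np.zeros(40), G)
        assert np.allclose(fit.b_hat, 0.0)
        assert fit.chi2 == 0.0

    def test_data_in_column_space_recovered_exactly(self, rng):
        th = vb.hz_to_internal([54.0], [430.0], 8000.0)
        G = vb.build_design_matrix(50, vb.ModelOrders(P=3, Q=1), th)
        c = rng.standard_normal(5)
        d = G.values @ c
        fit = vb.fit_period(d, G)
        assert np.allclose(fit.b_hat, c, atol=1e-10)
        assert fit.chi2 <= 1e-16 * float(d @ d)

    def test_matches_normal_equations(self, rng):
        th = vb.hz_to_internal([54.0, 22.0], [430.0, 1088.0], 8000.0)
        G = vb.build_design_matrix(60, vb.ModelOrders(P=5, Q=2), th)
        d = rng.standard_normal(60)
        fit = vb.fit_period(d, G)
        g = G.values.T @ G.values
        b_ne = np.linalg.solve(g, G.values.T @ d)
        assert np.allclose(fit.b_hat, b_ne, atol=1e-8)
        sign, logdet = np.linalg.slogdet(g)
        assert sign > 0
        assert fit.logdet_g == pytest.approx(logdet, abs=1e-8)

    def test_duplicate_frequency_is_singular(self):
        th = vb.FormantParams(alpha=(0.02, 0.02), omega=(0.3, 0.3 + 1e-15))
        j = np.arange(50)[:, None]
        S = np.hstack(
            [
                np.cos(j * np.array(th.omega)) * np.exp(-j * np.array(th.alpha)),
                np.sin(j * np.array(th.omega)) * np.exp(-j * np.array(th.alpha)),
            ]
        )
        with pytest.raises(np.linalg.LinAlgError, match="column"):
            vb.fit_period(np.ones(50), S)

    def test_chi2_never_increases_with_extra_column(self, rng):
        """Nested least squares: a richer basis fits at least as well."""
        th = vb.hz_to_internal([54.0], [430.0], 8000.0)
        d = rng.standard_normal(60)
        chi = []
        for P in (1, 2, 4, 8):
            G = vb.build_design_matrix(60, vb.ModelOrders(P=P, Q=1), th)
            chi.append(vb.fit_period(d, G).chi2)
        assert all(a >= b - 1e-12 for a, b in zip(chi, chi[1:]))

    def test_quadratic_form_decomposition(self, rng):
        """||d - G b||^2 = chi2_hat + (b - b_hat)^T g (b - b_hat) exactly."""
        th = vb.hz_to_internal([54.0], [430.0], 8000.0)
        G = vb.build_design_matrix(40, vb.ModelOrders(P=3, Q=1), th)
        d = rng.standard_normal(40)
        fit = vb.fit_period(d, G)
        g = G.values.T @ G.values
        for _ in range(5):
            b = rng.standard_normal(5)
            lhs = float((d - G.values @ b) @ (d - G.values @ b))
            db = b - fit.b_hat
            rhs = fit.chi2 + float(db @ g @ db)
            assert lhs == pytest.approx(rhs, rel=1e-10)


class TestSigmaHat:
    def test_zero_chi2(self):
        assert vb.sigma_hat([0.0, 0.0], N=100, n=2, m=5) == 0.0

    def test_unit_case(self):
        N, n, m = 100, 2, 5
        assert vb.sigma_hat([N - n * m + 1], N, n, m) == pytest.approx(1.0)

    def test_matches_integrand_argmax(self):
        """sigma_hat equals the grid argmax of the sigma-marginal integrand."""
        N, n, m, S = 50, 1, 9, 0.42
        expected = sigma_marginal_argmax(S, N, n, m)
        assert vb.sigma_hat([S], N, n, m) == pytest.approx(expected, rel=1e-3)

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(ValueError):
            vb.sigma_hat([1.0], N=9, n=2, m=5)


class TestIntegratedLikelihood:
    def test_sigma_bounds_shift_is_theta_independent(self):
        ps, orders, th, _ = tiny_instance(seed=1)
        cfg1 = vb.PriorConfig.preset("gamma", sigma_lo=1e-6, sigma_hi=1.0)
        cfg2 = vb.PriorConfig.preset("gamma", sigma_lo=1e-6, sigma_hi=100.0)
        # the sigma-prior normalization enters as -log log(hi/lo)
        expected = np.log(np.log(1e6)) - np.log(np.log(1e8))
        for seed in (1, 5):
            ps, orders, th, _ = tiny_instance(seed=seed)
            l1 = vb.log_integrated_likelihood(ps, orders, th, cfg1.for_Q(1)).log_LI
            l2 = vb.log_integrated_likelihood(ps, orders, th, cfg2.for_Q(1)).log_LI
            assert l2 - l1 == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exact_marginalization_oracle(self, seed):
        """Closed form within 0.1 nats of exact marginalization + quadrature."""
        ps, orders, th, Gs = tiny_instance(seed=seed)
        cfg = vb.PriorConfig.preset("gamma").for_Q(1)
        val = vb.log_integrated_likelihood(ps, orders, th, cfg)
        assert val.approx_ok, "instance should satisfy the validity condition"
        oracle = exact_log_integrated_likelihood(ps.periods, Gs, cfg)
        assert val.log_LI == pytest.approx(oracle, abs=0.1)

    def test_multi_period_oracle_agreement(self):
        ps, orders, th, Gs = tiny_instance(seed=101, n=3, N=24, P=2, Q=1)
        cfg = vb.PriorConfig.preset("gamma").for_Q(1)
        val = vb.log_integrated_likelihood(ps, orders, th, cfg)
        oracle = exact_log_integrated_likelihood(ps.periods, Gs, cfg)
        assert val.log_LI == pytest.approx(oracle, abs=0.1)

    def test_low_validity_ratio_flagged(self):
        """Noise-dominated data with a broad formant fails the approximation
        check: basis power / noise power is no longer >> 1/delta^2."""
        rng = np.random.default_rng(3)
        th = vb.hz_to_internal([400.0], [1000.0], 8000.0)  # heavy damping
        orders = vb.ModelOrders(P=1, Q=1)
        d = rng.standard_normal(60)  # pure noise, sigma_hat ~ 1
        ps = vb.PitchPeriodSet(periods=[d], fs=8000.0, norm_scale=1.0)
        cfg = vb.PriorConfig.preset("gamma")
        val = vb.log_integrated_likelihood(ps, orders, th, cfg.for_Q(1))
        assert not val.approx_ok

    def test_degenerate_data_rejected(self):
        th = vb.hz_to_internal([54.0], [430.0], 8000.0)
        orders = vb.ModelOrders(P=1, Q=1)
        d = np.zeros(30)  # chi2 identically zero
        ps = vb.PitchPeriodSet(periods=[d], fs=8000.0, norm_scale=1.0)
        with pytest.raises(ValueError):
            vb.log_integrated_likelihood(ps, orders, th, vb.PriorConfig.preset("gamma").for_Q(1))

    def test_order_violation_rejected(self):
        ps, orders, th, _ = tiny_instance(seed=2, N=16)
        with pytest.raises(ValueError):
            IntegratedLikelihoodEvaluator(
                ps, vb.ModelOrders(P=14, Q=1), vb.PriorConfig.preset("gamma").for_Q(1)
            )

    def test_fast_path_matches_full_evaluation(self, male_periods, gamma_prior):
        th = vb.hz_to_internal([54.0, 22.0], [430.0, 1088.0], 8000.0)
        ev = IntegratedLikelihoodEvaluator(
            male_periods, vb.ModelOrders(P=6, Q=2), gamma_prior.for_Q(2)
        )
        assert ev(th) == pytest.approx(ev.evaluate(th).log_LI, rel=1e-10)

    def test_finite_over_prior_box(self, male_periods, gamma_prior, rng):
        """No overflow anywhere in the prior box at realistic N."""
        cfg = gamma_prior.for_Q(3)
        ev = IntegratedLikelihoodEvaluator(male_periods, vb.ModelOrders(P=6, Q=3), cfg)
        for _ in range(25):
            u = rng.random(6)
            th = vb.prior_transform(u, cfg, 8000.0)
            assert np.isfinite(ev(th))


def test_order_constant_uses_log_gamma_safely():
    # N - nm ~ 150: the linear-scale Gamma would overflow, the log form must not
    cfg = vb.PriorConfig.preset("gamma")
    val = log_order_constant(N=200, n=3, m=12, cfg=cfg)
    assert np.isfinite(val)
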