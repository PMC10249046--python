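"""Laplace marginal likelihood, fits, profiles, tests and OSA residuals."""

import numpy as np
import pytest
from scipy import integrate, stats

from stagessm import (
    FitResult,
    LaplaceMLE,
    LatentStates,
    aicc,
    fit_mle,
    inner_mode,
    lrt,
    marginal_nll,
    osa_residuals,
    profile,
    rescale,
)
from stagessm.laplace import IdentifiabilityError
from stagessm.model import latent_nll_parts
from stagessm.simulate import (
    ScenarioSpec,
    preset_params,
    simulate_covariates,
    simulate_dataset,
)
from stagessm.types import Dataset

from conftest import tiny_model


class TestInnerMode:
    def test_gradient_at_mode_is_tiny(self):
        for seed in [0, 1, 2]:
            params, latent, data = tiny_model(n=4, T=5, seed=seed)
            res = inner_mode(params, data)
            assert res.converged
            # oracle check: central finite differences at the returned mode
            u = res.u_hat.to_vector()
            eps = 1e-5
            for k in [0, u.size // 2, u.size - 1]:
                e = np.zeros_like(u)
                e[k] = eps
                fd = (
                    latent_nll_parts(params, u + e, data, order=0)[0]
                    - latent_nll_parts(params, u - e, data, order=0)[0]
                ) / (2 * eps)
                assert abs(fd) < 1e-4

    def test_newton_exact_on_gaussian_joint(self):
        """With log-link survival the joint is exactly quadratic in the
        latent block, so the mode solves the normal equations directly."""
        params, latent, data = tiny_model(n=3, T=4, seed=1)
        u0 = latent.to_vector()
        nll0, g0, H0 = latent_nll_parts(params, u0, data,
                                        survival_link="log")
        expected = u0 - np.linalg.solve(H0, g0)
        res = inner_mode(params, data, survival_link="log")
        assert np.allclose(res.u_hat.to_vector(), expected, atol=1e-8)

    def test_tight_observations_pin_latent_states(self):
        params, latent, data = tiny_model(n=3, T=4, seed=4, sigma_o=1e-4)
        res = inner_mode(params, data)
        # the latent mode must reproduce the abundances implied by the data
        from stagessm import build_abundances

        N_hat = build_abundances(params.log_N_init, res.u_hat)
        psi = np.array([params.psi[s] for s in data.survey_of_stage])
        assert np.allclose(psi[:, None] * N_hat, data.Y, rtol=1e-3)


class TestMarginalNll:
    def test_equals_linear_gaussian_closed_form(self):
        """In the all-log-normal variant the Laplace approximation is exact
        and must match the closed-form Gaussian marginal."""
        params, latent, data = tiny_model(n=3, T=4, seed=8)
        got = marginal_nll(params, data, survival_link="log")

        # independent construction: log Y is multivariate normal
        n, T = data.n_stages, data.T
        m_R = data.covariates.w_R @ params.beta_R
        m_S = np.vstack([w @ b for w, b in
                         zip(data.covariates.w_S, params.beta_S)])
        means = {}
        # mean/cov of log N via the linear recursion over latent normals
        # enumerate latent variables: (rho, t) and (phi, i, t)
        idx = {("r", t): t for t in range(T)}
        for i in range(n - 1):
            for t in range(T):
                idx[("s", i, t)] = T + i * T + t
        dim = n * T
        mu_lat = np.zeros(dim)
        var_lat = np.zeros(dim)
        for t in range(T):
            mu_lat[t] = m_R[t]
            var_lat[t] = params.sigma_p_R**2
        for i in range(n - 1):
            for t in range(T):
                mu_lat[T + i * T + t] = m_S[i, t]
                var_lat[T + i * T + t] = params.sigma_p_S[i] ** 2
        # coefficient row of log N_{i,t} on the latent vector
        rows = {}
        for t in range(T):
            for i in range(n):
                row = np.zeros(dim)
                for tp in range(t + 1):
                    row[idx[("r", tp)]] = 1.0
                    top = n - 1 if tp < t else i
                    for k in range(top):
                        row[idx[("s", k, tp)]] = 1.0
                rows[(i, t)] = row
        obs = [(i, t) for i in range(n) for t in range(T)
               if np.isfinite(data.Y[i, t])]
        A = np.array([rows[o] for o in obs])
        so = np.array([data.sigma_o[o] for o in obs])
        psi = np.array([params.psi[data.survey_of_stage[i]]
                        for i, _ in obs])
        mean_ly = np.log(psi) + params.log_N_init + A @ mu_lat - so**2 / 2
        cov_ly = (A * var_lat) @ A.T + np.diag(so**2)
        ly = np.log(np.array([data.Y[o] for o in obs]))
        ll = stats.multivariate_normal.logpdf(ly, mean_ly, cov_ly)
        if data.Y_init is not None:
            s0 = data.sigma_o_init
            psi_n = params.psi[data.survey_of_stage[-1]]
            ll += stats.norm.logpdf(
                np.log(data.Y_init),
                np.log(psi_n) + params.log_N_init - s0**2 / 2,
                s0,
            )
        assert got == pytest.approx(-ll, abs=1e-8)

    def test_close_to_quadrature_on_single_cohort(self):
        """Laplace vs adaptive 2-D quadrature of the exact marginal."""
        params, latent, data = tiny_model(n=2, T=1, seed=3)
        got = marginal_nll(params, data)

        def joint_density(x_s, lr):
            u = np.array([lr, x_s])
            nll = latent_nll_parts(params, u, data, order=0)[0]
            return np.exp(-nll)

        val, _ = integrate.dblquad(
            joint_density, -8, 8, lambda _: -8, lambda _: 8,
            epsabs=1e-12, epsrel=1e-10,
        )
        exact = -np.log(val)
        assert got == pytest.approx(exact, rel=0.01)

    def test_invariant_under_rescale_when_all_psi_free(self):
        params, latent, data = tiny_model(n=3, T=4, seed=6)
        base = marginal_nll(params, data)
        moved = marginal_nll(rescale(params, 3.0), data)
        assert moved == pytest.approx(base, rel=1e-8)


class TestFit:
    def test_near_deterministic_limit_recovers_coefficients(self):
        spec = ScenarioSpec("low", False, seed=21)
        params = preset_params(spec)
        params.sigma_p_R = 0.002
        params.sigma_p_S = np.full(3, 0.002)
        cov = simulate_covariates(20, 1, seed=21)
        data, _ = simulate_dataset(params, cov, 0.002, seed=21)
        fit = fit_mle(data, fix_spec={s: 1.0 for s in data.surveys})
        est = dict(zip(fit.free_names, fit.free_values))
        assert est["beta_R_0"] == pytest.approx(1.0, rel=0.01)
        assert est["beta_R_1"] == pytest.approx(-0.5, rel=0.01)
        assert est["beta_S1_1"] == pytest.approx(1.3, rel=0.01)
        assert est["log_N_init"] == pytest.approx(13.82, rel=0.01)

    def test_unidentifiable_spec_refused(self, low_biased):
        data, _, _ = low_biased
        with pytest.raises(IdentifiabilityError):
            LaplaceMLE(fix_psi={}).fit(data)

    def test_fixed_n_init_is_accepted_instead(self, low_biased):
        data, _, params = low_biased
        est = LaplaceMLE(fix_psi={}, fix_log_N_init=params.log_N_init,
                         compute_vcov=False, maxiter=60)
        est.fit(data)
        assert "log_N_init" not in est.free_names_

    def test_estimates_near_truth_high_information(self, high_fit):
        est = dict(zip(high_fit.free_names, high_fit.free_values))
        # psi_4 fixed at its wrong value 1 -> adjusted truths apply
        assert est["beta_R_1"] == pytest.approx(-1.0, abs=0.3)
        assert est["beta_S1_1"] == pytest.approx(2.0, abs=0.4)
        assert np.exp(est["log_psi_S2"]) == pytest.approx(0.2, rel=0.3)
        assert est["log_N_init"] == pytest.approx(13.82 - np.log(2), abs=0.2)

    def test_sklearn_param_interface(self):
        est = LaplaceMLE(fix_psi={"S4": 1.0})
        got = est.get_params()
        assert got["fix_psi"] == {"S4": 1.0}
        est.set_params(maxiter=77)
        assert est.maxiter == 77


@pytest.fixture(scope="module")
def small_fit():
    params, latent, data = tiny_model(n=3, T=20, seed=14, sigma_o=0.08)
    fix = {s: params.psi[s] for s in data.surveys}
    return fit_mle(data, fix_spec=fix)


class TestProfile:

    def test_profile_at_mle_equals_fit(self, small_fit):
        est = dict(zip(small_fit.free_names, small_fit.free_values))
        prof = profile(small_fit, "beta_R_0",
                       np.array([est["beta_R_0"]]))
        assert prof.loglik[0] == pytest.approx(small_fit.loglik, abs=1e-4)

    def test_profile_below_unconstrained_max(self, small_fit):
        est = dict(zip(small_fit.free_names, small_fit.free_values))
        grid = est["beta_R_0"] + np.linspace(-0.6, 0.6, 7)
        prof = profile(small_fit, "beta_R_0", grid)
        assert np.all(prof.loglik <= small_fit.loglik + 1e-6)

    def test_quadratic_drop_matches_wald_interval(self, small_fit):
        """The 1.92-drop crossing of a near-quadratic profile sits near the
        +-1.96 SE Wald limits."""
        est = dict(zip(small_fit.free_names, small_fit.free_values))
        se = dict(zip(small_fit.free_names, small_fit.se()))
        p, s = est["beta_R_0"], se["beta_R_0"]
        grid = p + np.linspace(-3 * s, 3 * s, 25)
        prof = profile(small_fit, "beta_R_0", grid)
        drop = small_fit.loglik - prof.loglik
        # interpolate where the drop crosses 1.92 on each side
        right = grid[grid > p]
        d_right = np.interp(right, grid, drop)
        cross_right = np.interp(1.92, d_right, right)
        assert cross_right - p == pytest.approx(1.96 * s, rel=0.10)

    def test_joint_profile_grid(self, small_fit):
        est = dict(zip(small_fit.free_names, small_fit.free_values))
        pts = [
            (est["beta_R_0"], est["beta_R_1"]),
            (est["beta_R_0"] + 0.3, est["beta_R_1"] - 0.3),
        ]
        prof = profile(small_fit, ["beta_R_0", "beta_R_1"], pts)
        assert prof.loglik[0] == pytest.approx(small_fit.loglik, abs=1e-4)
        assert prof.loglik[1] < prof.loglik[0]


class TestModelComparison:
    def test_likelihood_ratio_statistics_from_reported_fits(self):
        stat, df, p = lrt(-183.24, -120.21, df=2)
        assert stat == pytest.approx(126.06, abs=1e-9)
        assert p < 0.01
        stat2, df2, p2 = lrt(-120.21, -111.00, df=1)
        assert stat2 == pytest.approx(18.42, abs=1e-9)
        assert p2 < 0.01

    def test_identical_fits_give_zero(self):
        stat, df, p = lrt(-50.0, -50.0, df=0)
        assert stat == 0.0
        assert p == 1.0

    def test_nested_free_sets_checked(self):
        a = FitResult(None, -10.0, True, True, 80, ["x", "y"])
        b = FitResult(None, -9.0, True, True, 80, ["x", "z"])
        with pytest.raises(ValueError):
            lrt(a, b)

    def test_decreasing_loglik_warns(self):
        with pytest.warns(RuntimeWarning):
            lrt(-10.0, -12.0, df=1)

    def test_aicc_limits(self):
        fit0 = FitResult(None, -100.0, True, True, 500, [])
        assert aicc(fit0) == pytest.approx(200.0)
        k5 = [f"p{i}" for i in range(5)]
        small = FitResult(None, -100.0, True, True, 80, k5)
        big = FitResult(None, -100.0, True, True, 10**7, k5)
        assert aicc(big) == pytest.approx(-2 * -100.0 + 10, rel=1e-5)
        assert aicc(small) > aicc(big)
        with pytest.raises(ValueError):
            aicc(FitResult(None, -1.0, True, True, 6, k5))


class TestOsaResiduals:
    def test_calibrated_under_true_model(self):
        spec = ScenarioSpec("high", True, seed=33)
        params = preset_params(spec)
        cov = simulate_covariates(20, 1, seed=33)
        data, _ = simulate_dataset(params, cov, 0.05, seed=33)
        fit = FitResult(params, 0.0, True, True, data.n_obs, [], data=data)
        res = osa_residuals(fit)
        z = res["residual"].to_numpy()
        assert abs(z.mean()) < 3 / np.sqrt(z.size)
        assert 0.8 <= z.var() <= 1.2

    def test_noise_free_path_gives_vanishing_residuals(self):
        """Observations placed exactly on the model's predictive path leave
        zero innovations at every step."""
        from scipy.special import expit

        from stagessm import LatentStates, build_abundances
        from stagessm.model import process_means
        from stagessm.types import Dataset

        params = preset_params(ScenarioSpec("low", True, seed=7))
        cov = simulate_covariates(20, 1, seed=7)
        m_R, m_S = process_means(params, cov)
        latent = LatentStates(m_R.copy(), m_S.copy())
        N = build_abundances(params.log_N_init, latent)
        psi = np.array(list(params.psi.values()))
        so = 0.1
        Y = psi[:, None] * N * np.exp(-(so**2) / 2)
        data = Dataset(
            Y=Y, sigma_o=np.full((4, 20), so), covariates=cov,
            Y_init=float(psi[-1] * np.exp(params.log_N_init - so**2 / 2)),
            sigma_o_init=so,
        )
        fit = FitResult(params, 0.0, True, True, data.n_obs, [], data=data)
        res = osa_residuals(fit)
        assert np.max(np.abs(res["residual"])) < 1e-8

    def test_ignored_bias_leaves_systematic_stage_pattern(self):
        """Fitting with all psi = 1 to biased data leaves a systematic
        stage-3 underprediction (positive residual mean)."""
        spec = ScenarioSpec("low", True, seed=17)
        params = preset_params(spec)
        cov = simulate_covariates(20, 1, seed=17)
        data, _ = simulate_dataset(params, cov, 0.1, seed=17)
        fit = fit_mle(data, fix_spec={s: 1.0 for s in data.surveys},
                      compute_vcov=False)
        res = osa_residuals(fit)
        z3 = res.loc[res["stage"] == 3, "residual"].to_numpy()
        zall = res["residual"].to_numpy()
        # residuals are far from standard-normal calibration for stage 3
        assert abs(z3.mean()) > 3 / np.sqrt(z3.size)
        assert z3.mean() > 0
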