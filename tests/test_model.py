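"""Spatial model: covariance structure, priors, joint density, MCMC behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import atlas
from atlas import (InferenceConfig, PriorSpec, SimulationTruth, build_distance_matrix,
                   default_priors, exp_cov, fit_binomial_glm, fit_spatial_binomial,
                   generate_domain, log_posterior)
from atlas.simulate import simulate_study


class TestDistanceMatrix:
    def test_three_four_five(self):
        D = build_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)
        assert np.all(np.diag(D) == 0)

    def test_matches_pairwise_loop_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(50, 2))
        D = build_distance_matrix(pts)
        for i in range(50):
            for j in range(50):
                d = np.sqrt(((pts[i] - pts[j]) ** 2).sum())
                assert abs(D[i, j] - d) < 1e-12

    def test_duplicate_locations_warn(self):
        with pytest.warns(RuntimeWarning, match="duplicated"):
            build_distance_matrix(np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestExpCov:
    def test_zero_distance_gives_variance(self):
        S = exp_cov(np.zeros((2, 2)), 0.7, 0.1)
        assert S[0, 0] == pytest.approx(0.7)

    def test_correlation_at_one_range_is_exp_minus_3(self):
        phi = 0.075
        D = np.array([[0.0, 3.0 / phi], [3.0 / phi, 0.0]])
        S = exp_cov(D, 1.0, phi)
        assert S[0, 1] == pytest.approx(np.exp(-3.0), abs=1e-12)

    def test_large_phi_independence_limit(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        S = exp_cov(D, 2.0, 1e6)
        assert S[0, 1] == pytest.approx(0.0, abs=1e-300)
        assert S[0, 0] == pytest.approx(2.0)


class TestPriors:
    def test_r0_is_five_percent_of_width(self):
        dom = generate_domain(2, 2, 50.0)  # 100 km wide
        assert default_priors(dom).r0 == pytest.approx(5.0)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            default_priors(0.0)

    def test_override_passthrough(self):
        dom = generate_domain(2, 2, 50.0)
        assert default_priors(dom, r0=12.0).r0 == 12.0

    def test_pc_prior_tail_probabilities_integrate(self):
        # P(range < r0) = alpha under the PC prior density used
        spec = PriorSpec(r0=10.0)
        lam = -10.0 * np.log(spec.alpha_range)
        # closed form of the integral: P(r < r0) = exp(-lam / r0)
        assert np.exp(-lam / 10.0) == pytest.approx(spec.alpha_range)
        # sigma prior: standard direction puts alpha mass above sigma_u
        lam_s = -np.log(spec.alpha_sigma) / spec.sigma_u
        assert np.exp(-lam_s * spec.sigma_u) == pytest.approx(spec.alpha_sigma)

    def test_doubling_beta_prior_variance_shifts_density_by_known_constant(self):
        p1 = PriorSpec(r0=5.0, beta_sd2=1000.0)
        p2 = PriorSpec(r0=5.0, beta_sd2=2000.0)
        beta = np.array([1.0, -2.0])
        delta = p1.log_prior_beta(beta) - p2.log_prior_beta(beta)
        expected = (-0.5 * 2 * np.log(1000 / 2000)
                    - 0.5 * float(beta @ beta) * (1 / 1000 - 1 / 2000))
        assert delta == pytest.approx(expected, abs=1e-12)

    def test_invalid_switch_values_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(r0=5.0, sigma_prior_direction="upside_down")
        with pytest.raises(ValueError):
            PriorSpec(r0=5.0, iid_prior="nope")


def _toy_data(n, p, seed, phi=0.075):
    r = np.random.default_rng(seed)
    locs = r.uniform(0, 100, size=(n, 2))
    X = np.column_stack([np.ones(n), r.normal(size=(n, p - 1))])
    y = r.binomial(22, 0.4, n).astype(float)
    m = np.full(n, 22.0)
    D = build_distance_matrix(locs)
    return {"X": X, "y": y, "m": m, "D": D}


class TestLogPosterior:
    def test_matches_naive_scipy_oracle(self, rng):
        data = _toy_data(25, 3, 42)
        priors = PriorSpec(r0=5.0)
        beta = rng.normal(size=3) * 0.5
        omega = rng.normal(size=25) * 0.3
        eps = rng.normal(size=25) * 0.1
        theta = np.array([np.log(0.5), np.log(0.06), np.log(0.2)])
        got = log_posterior(beta, omega, theta, data, priors, eps=eps)

        # naive term-by-term oracle via scipy distributions
        s2w, phi, s2e = np.exp(theta)
        eta = data["X"] @ beta + omega + eps
        ll = stats.binom.logpmf(data["y"], data["m"], expit(eta)).sum()
        S = s2w * np.exp(-phi * data["D"]) + 1e-8 * s2w * np.eye(25)
        ll += stats.multivariate_normal.logpdf(omega, mean=np.zeros(25), cov=S)
        ll += stats.norm.logpdf(eps, 0, np.sqrt(s2e)).sum()
        ll += stats.norm.logpdf(beta, 0, np.sqrt(priors.beta_sd2)).sum()
        # hyperpriors: sill PC (exponential on sigma), range PC, gamma on precision
        sigma = np.sqrt(s2w)
        lam_s = -np.log(priors.alpha_sigma) / priors.sigma_u
        ll += stats.expon.logpdf(sigma, scale=1 / lam_s) + np.log(sigma / 2)
        rng_km = 3.0 / phi
        lam_r = -priors.r0 * np.log(priors.alpha_range)
        ll += (np.log(lam_r) - 2 * np.log(rng_km) - lam_r / rng_km) + np.log(rng_km)
        tau = 1 / s2e
        ll += stats.gamma.logpdf(tau, a=2, scale=1.0) + np.log(tau)
        assert got == pytest.approx(ll, abs=1e-8)

    def test_binomial_term_closed_form_at_half(self):
        n, m = 10, 8
        data = _toy_data(n, 1, 7)
        data["y"] = np.full(n, m / 2)
        data["m"] = np.full(n, float(m))
        priors = PriorSpec(r0=5.0)
        theta = np.array([np.log(0.3), np.log(0.05), np.log(0.1)])
        got = log_posterior(np.zeros(1), np.zeros(n), theta, data, priors)
        # subtracting every non-likelihood term leaves n*[log C(m,m/2) + m log 1/2]
        S = 0.3 * np.exp(-0.05 * data["D"]) + 1e-8 * 0.3 * np.eye(n)
        rest = stats.multivariate_normal.logpdf(np.zeros(n), cov=S)
        rest += stats.norm.logpdf(0.0, 0, np.sqrt(priors.beta_sd2))
        rest += priors.log_prior_theta(theta)
        from scipy.special import comb
        expected_ll = n * (np.log(comb(m, m // 2)) + m * np.log(0.5))
        assert got - rest == pytest.approx(expected_ll, abs=1e-8)

    def test_non_positive_definite_covariance_raises(self):
        # a distance matrix violating the triangle inequality makes exp(-phi D)
        # indefinite
        D = np.array([[0.0, 0.1, 8.0], [0.1, 0.0, 0.1], [8.0, 0.1, 0.0]])
        data = {"X": np.ones((3, 1)), "y": np.array([1.0, 1, 1]),
                "m": np.array([5.0, 5, 5]), "D": D}
        with pytest.raises(np.linalg.LinAlgError):
            log_posterior(np.zeros(1), np.zeros(3), np.log([1.0, 1.0, 0.1]),
                          data, PriorSpec(r0=5.0))


def _study(n, seed, sigma2_omega=0.5, range_km=40.0, sigma2_eps=0.0,
           beta=(-1.0, 0.5, -0.3)):
    dom = generate_domain(4, 4, 50.0)
    truth = SimulationTruth.from_range(beta=beta, sigma2_omega=sigma2_omega,
                                       range_km=range_km, sigma2_eps=sigma2_eps,
                                       seed=seed)
    clusters, grids = simulate_study(dom, n, truth)
    return dom, truth, clusters, grids


class TestFitSpatialBinomial:
    def test_reduces_to_bayesian_logistic_regression(self):
        # with both variance components pinned to ~zero the posterior mean of
        # beta must sit within 2 posterior SDs of the GLM MLE
        dom, truth, cl, _ = _study(150, seed=31, sigma2_omega=1e-6, range_km=40.0)
        cfg = InferenceConfig(seed=5, n_iter=1500, burn_in=500,
                              fix_sigma2_omega=1e-8, fix_phi=0.075, fix_sigma2_eps=1e-8)
        fit = fit_spatial_binomial(cl, ["cov_1", "cov_2"], default_priors(dom), cfg)
        X = np.column_stack([np.ones(len(cl)), cl[["cov_1", "cov_2"]].to_numpy()])
        mle = fit_binomial_glm(X, cl["y_events"].to_numpy(float),
                               cl["m"].to_numpy(float)).coefficients
        for j in range(3):
            mean = fit.beta_summary["mean"][j]
            sd = fit.beta_summary["sd"][j]
            assert abs(mean - mle[j]) < 2 * sd

    def test_flat_signal_posterior_prevalence_half(self):
        dom, _, cl, _ = _study(80, seed=32)
        cl = cl.copy()
        cl["m"] = 22
        cl["y_events"] = 11
        cfg = InferenceConfig(seed=2, n_iter=1500, burn_in=500)
        fit = fit_spatial_binomial(cl, [], default_priors(dom), cfg)
        assert np.all(np.abs(fit.latent_p["mean"] - 0.5) < 0.07)
        assert np.all(fit.latent_p["mean"].between(0, 1))

    def test_same_seed_identical_summaries(self):
        dom, _, cl, _ = _study(60, seed=33)
        cfg = InferenceConfig(seed=9, n_iter=400, burn_in=100)
        f1 = fit_spatial_binomial(cl, ["cov_1"], default_priors(dom), cfg)
        f2 = fit_spatial_binomial(cl, ["cov_1"], default_priors(dom), cfg)
        pd.testing.assert_frame_equal(f1.beta_summary, f2.beta_summary)
        pd.testing.assert_frame_equal(f1.hyper_summary, f2.hyper_summary)
        np.testing.assert_array_equal(f1.draws["u"], f2.draws["u"])

    def test_quantiles_ordered_and_range_consistent(self):
        dom, _, cl, _ = _study(60, seed=34)
        cfg = InferenceConfig(seed=4, n_iter=600, burn_in=200)
        fit = fit_spatial_binomial(cl, ["cov_1"], default_priors(dom), cfg)
        for df in (fit.beta_summary, fit.hyper_summary):
            assert (df["q2.5"] <= df["q50"]).all()
            assert (df["q50"] <= df["q97.5"]).all()
        np.testing.assert_allclose(fit.draws["range_km"], 3.0 / fit.draws["phi"],
                                   rtol=1e-12)

    def test_posterior_contraction_with_more_data(self):
        # average posterior SD of beta must not grow when n doubles
        sds_small, sds_large = [], []
        for s in range(6):
            _, _, cl_s, _ = _study(60, seed=700 + s)
            _, _, cl_l, _ = _study(120, seed=800 + s)
            dom = generate_domain(4, 4, 50.0)
            cfg = InferenceConfig(seed=s, n_iter=800, burn_in=300)
            f_s = fit_spatial_binomial(cl_s, ["cov_1", "cov_2"], default_priors(dom), cfg)
            f_l = fit_spatial_binomial(cl_l, ["cov_1", "cov_2"], default_priors(dom), cfg)
            sds_small.append(f_s.beta_summary["sd"].mean())
            sds_large.append(f_l.beta_summary["sd"].mean())
        assert np.mean(sds_large) <= np.mean(sds_small)

    def test_range_recovered_to_factor_of_two_in_most_replicates(self):
        # weak identifiability of (sigma2_omega, phi, sigma2_eps) is expected;
        # the posterior median of the range should still usually land within a
        # factor of 2 of the generative 40 km
        hits = 0
        for s in range(6):
            _, _, cl, _ = _study(250, seed=900 + s)
            dom = generate_domain(4, 4, 50.0)
            cfg = InferenceConfig(seed=s, n_iter=2000, burn_in=700)
            fit = fit_spatial_binomial(cl, ["cov_1", "cov_2"], default_priors(dom), cfg)
            med = float(fit.hyper_summary.set_index("name").loc["range_km", "q50"])
            hits += 20.0 <= med <= 80.0
        assert hits >= 4

    def test_save_load_round_trip(self, tmp_path):
        dom, _, cl, _ = _study(50, seed=35)
        cfg = InferenceConfig(seed=1, n_iter=300, burn_in=100)
        fit = fit_spatial_binomial(cl, ["cov_1"], default_priors(dom), cfg)
        fit.save(tmp_path / "fit")
        loaded = atlas.model.ModelFit.load(tmp_path / "fit")
        pd.testing.assert_frame_equal(fit.beta_summary, loaded.beta_summary)
        np.testing.assert_array_equal(fit.draws["beta"], loaded.draws["beta"])
        assert loaded.covariate_names == fit.covariate_names
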