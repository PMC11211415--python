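"""Ordinal trajectory-mixture likelihood, fitting and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from tmstraj.ingest import ratings_to_matrix, recode_ordinal
from tmstraj.lcga import (
    FitSettings,
    LCGAParams,
    category_prob,
    expected_rating,
    fit_lcga,
    fit_lcga_em,
    posterior_probs,
    predict_trajectory,
    subject_loglik,
)
from tmstraj.lcga import _Encoded, _nll_grad, observed_information


def flat_params(G=1, tau=(0.0, 1.0, 2.0)):
    return LCGAParams(betas=np.zeros((G, 4)), tau=np.asarray(tau))


class TestCategoryProb:
    def test_standard_normal_table_values(self):
        p = flat_params()
        expected = [0.5000, 0.3413, 0.1359, 0.0228]
        got = [category_prob(p, 0, 0, m) for m in range(1, 5)]
        assert np.allclose(got, expected, atol=5e-5)

    @pytest.mark.parametrize("lam0", [-2.0, 0.0, 0.7, 3.0])
    def test_probabilities_sum_to_one(self, lam0):
        p = LCGAParams(betas=[[lam0, 1.0, -0.5, 0.2]], tau=[0, 0.8, 1.9])
        for t in (0, 7, 20):
            total = sum(category_prob(p, 0, t, m) for m in range(1, 5))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_large_latent_saturates_top_category(self):
        p = LCGAParams(betas=[[40.0, 0, 0, 0]], tau=[0, 1, 2])
        assert category_prob(p, 0, 5, 4) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError):
            category_prob(flat_params(), 0, 0, 5)

    def test_matches_cumulative_probit_definition(self):
        p = LCGAParams(betas=[[0.4, 2.0, -1.0, 0.5]], tau=[0, 1.1, 2.2])
        t = 13
        u = t / 20
        lam = 0.4 + 2 * u - u**2 + 0.5 * u**3
        expected = norm.cdf(2.2 - lam) - norm.cdf(1.1 - lam)
        assert category_prob(p, 0, t, 3) == pytest.approx(expected, abs=1e-12)


class TestSubjectLoglik:
    def test_single_class_single_point(self):
        p = flat_params()
        # category 1 at lambda=0 with tau_1=0 has probability 0.5
        assert subject_loglik(p, [0], [1]) == pytest.approx(np.log(0.5))

    def test_empty_series_contributes_zero(self):
        with pytest.warns(UserWarning):
            assert subject_loglik(flat_params(), [1, 2], [np.nan, np.nan]) == 0.0

    def test_missing_sessions_drop_out(self):
        p = LCGAParams(betas=[[0.3, 1, 0, 0]], tau=[0, 1, 2])
        full = subject_loglik(p, [1, 2], [2, np.nan])
        only = subject_loglik(p, [1], [2])
        assert full == pytest.approx(only)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_enumeration(self, seed):
        # tiny grids: <= 3 subjects x 3 sessions x 4 categories
        rng = np.random.default_rng(seed)
        G = rng.integers(1, 4)
        p = LCGAParams(
            betas=rng.normal(0, 1, (G, 4)),
            tau=np.concatenate([[0.0], np.sort(rng.uniform(0.3, 2.5, 2))]),
            zeta=rng.normal(0, 1, G - 1),
        )
        sessions = rng.choice(21, size=3, replace=False)
        for _ in range(3):
            values = rng.integers(1, 5, size=3).astype(float)
            values[rng.random(3) < 0.3] = np.nan
            obs = ~np.isnan(values)
            pi = p.pi
            brute = 0.0
            for g in range(G):
                prod = pi[g]
                for t, v in zip(sessions[obs], values[obs]):
                    prod *= category_prob(p, g, t, int(v))
                brute += prod
            expected = np.log(brute) if obs.any() else 0.0
            if obs.any():
                assert subject_loglik(p, sessions, values) == pytest.approx(expected, abs=1e-10)


class TestGradient:
    def test_analytic_gradient_matches_central_differences(self):
        rng = np.random.default_rng(1)
        Y = rng.integers(1, 5, size=(10, 5)).astype(float)
        Y[0, 1] = np.nan
        enc = _Encoded(Y, np.array([0, 5, 10, 15, 20.0]), 4)
        G = 3
        x = rng.normal(0, 0.7, size=(G - 1) + 4 * G + 2)
        _, g_ana = _nll_grad(x, enc, G)
        g_num = np.zeros_like(x)
        for j in range(len(x)):
            h = 1e-6 * max(1, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            g_num[j] = (_nll_grad(xp, enc, G)[0] - _nll_grad(xm, enc, G)[0]) / (2 * h)
        assert np.allclose(g_ana, g_num, rtol=1e-5, atol=1e-6)


class TestMembershipCovariates:
    def test_gradient_with_covariates_matches_central_differences(self):
        rng = np.random.default_rng(7)
        Y = rng.integers(1, 5, size=(12, 4)).astype(float)
        enc = _Encoded(Y, np.array([0, 7, 14, 20.0]), 4, covariates=rng.normal(0, 1, (12, 2)))
        G = 2
        x = rng.normal(0, 0.5, size=(G - 1) * (1 + 2) + 4 * G + 2)
        _, g_ana = _nll_grad(x, enc, G)
        for j in range(len(x)):
            h = 1e-6 * max(1, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            num = (_nll_grad(xp, enc, G)[0] - _nll_grad(xm, enc, G)[0]) / (2 * h)
            assert g_ana[j] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_wald_test_on_uninformative_covariate(self, medium_cohort):
        # a pure-noise covariate should not predict class membership
        from tmstraj.lcga import wald_test_membership

        rat = recode_ordinal(medium_cohort.ratings)
        rng = np.random.default_rng(0)
        cov = rng.normal(0, 1, (medium_cohort.config.n_subjects, 1))
        fit = fit_lcga(rat, 2, n_starts=3, seed=0, covariates=cov)
        assert fit.params.gamma is not None
        res = wald_test_membership(fit, rat, cov)
        assert 0 <= res["p_value"] <= 1
        assert res["p_value"] > 0.01
        assert res["df"] == 1


class TestPosteriors:
    def test_flat_likelihood_returns_prior(self):
        # identical classes: posterior equals pi for every subject
        p = LCGAParams(betas=np.zeros((2, 4)), tau=[0, 1, 2], zeta=[0.9])
        Y = np.array([[1.0, 3.0], [2.0, 2.0]])
        post = posterior_probs(p, (Y, np.array([1.0, 2.0])))
        assert np.allclose(post, p.pi, atol=1e-12)

    def test_single_class_posterior_is_one(self):
        p = flat_params()
        post = posterior_probs(p, (np.array([[2.0, 3.0]]), np.array([1.0, 2.0])))
        assert np.allclose(post, 1.0)

    def test_hand_computed_two_class_one_observation(self):
        p = LCGAParams(betas=[[0.0, 0, 0, 0], [1.5, 0, 0, 0]], tau=[0, 1, 2], zeta=[0.5])
        t, y = 4, 3
        pi = p.pi
        lik = np.array([category_prob(p, g, t, y) for g in range(2)])
        expected = pi * lik / (pi * lik).sum()
        post = posterior_probs(p, (np.array([[float(y)]]), np.array([float(t)])))
        assert np.allclose(post[0], expected, atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        p = LCGAParams(
            betas=rng.normal(0, 2, (4, 4)),
            tau=[0, 1.2, 2.4],
            zeta=rng.normal(0, 1, 3),
        )
        Y = rng.integers(1, 5, (30, 8)).astype(float)
        post = posterior_probs(p, (Y, np.linspace(0, 20, 8)))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestFitting:
    def test_one_class_recovers_marginal_frequencies(self):
        # closed form: probit inversion of the empirical cumulative frequencies
        rng = np.random.default_rng(0)
        tau_true = np.array([0.0, 0.9, 1.8])
        lam_true = 0.7
        n = 4000
        latent = lam_true + rng.standard_normal(n)
        cats = 1 + np.searchsorted(tau_true, latent)
        Y = cats[:, None].astype(float)
        fit = fit_lcga((Y, np.array([10.0])), G=1, n_starts=1, seed=0)
        freq = np.bincount(cats, minlength=5)[1:] / n
        cum = np.cumsum(freq)[:-1]
        # model cumulative P(Y <= m) = Phi(tau_m - lambda(u))
        lam_fit = fit.params.latent([10.0])[0, 0]
        implied = norm.cdf(fit.params.tau - lam_fit)
        assert np.allclose(implied, cum, atol=0.02)

    def test_two_opposite_subjects_perfectly_separated(self):
        sessions = np.arange(1, 21, dtype=float)
        Y = np.vstack([np.ones(20), np.full(20, 4.0)])
        fit = fit_lcga((Y, sessions), G=2, n_starts=6, seed=0)
        assert fit.posteriors.max(axis=1).min() > 0.99
        assert np.allclose(np.sort(fit.params.pi), [0.5, 0.5], atol=1e-3)

    def test_invalid_g_rejected(self):
        with pytest.raises(ValueError):
            fit_lcga((np.ones((2, 2)), np.array([1.0, 2.0])), G=0)

    def test_assignments_are_argmax_and_rows_normalised(self, medium_cohort):
        rat = recode_ordinal(medium_cohort.ratings)
        fit = fit_lcga(rat, 2, n_starts=3, seed=0)
        assert np.array_equal(fit.assignments, fit.posteriors.argmax(axis=1))
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_canonical_class_order_best_first(self, medium_cohort):
        rat = recode_ordinal(medium_cohort.ratings)
        fit = fit_lcga(rat, 3, n_starts=5, seed=2)
        lam_end = fit.params.latent([20.0])[:, 0]
        assert np.all(np.diff(lam_end) <= 0)

    def test_serialization_roundtrip(self, medium_cohort, tmp_path):
        rat = recode_ordinal(medium_cohort.ratings)
        fit = fit_lcga(rat, 2, n_starts=3, seed=0)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        import json

        d = json.loads(path.read_text())
        p = LCGAParams.from_dict(d["params"])
        assert np.allclose(p.betas, fit.params.betas)
        assert d["n_subjects"] == fit.n_subjects


class TestEMCrossCheck:
    def test_loglik_monotone_and_agrees_with_qn(self, medium_cohort):
        rat = recode_ordinal(medium_cohort.ratings)
        em = fit_lcga_em(rat, 2, settings=FitSettings(max_iter=60, seed=0))
        trace = np.array(em.start_logliks)
        assert np.all(np.diff(trace) >= -1e-6)  # monotone up to inner tolerance
        qn = fit_lcga(rat, 2, n_starts=5, seed=0)
        # EM is a cross-check: same optimum within a small gap
        assert em.loglik == pytest.approx(qn.loglik, abs=2.0)


class TestPredictTrajectory:
    def _fit(self, medium_cohort):
        rat = recode_ordinal(medium_cohort.ratings)
        return rat, fit_lcga(rat, 2, n_starts=3, seed=0)

    def test_zero_covariance_collapses_bands(self, medium_cohort):
        _, fit = self._fit(medium_cohort)
        k = len(fit.params.betas.ravel()) + len(fit.params.zeta) + fit.params.M - 2
        traj = predict_trajectory(fit, vcov=np.zeros((k, k)), n_draws=50, seed=0)
        assert np.allclose(traj["lo95"], traj["expected_rating"], atol=1e-12)
        assert np.allclose(traj["hi95"], traj["expected_rating"], atol=1e-12)

    def test_bands_contain_point_curve_and_stay_in_range(self, medium_cohort):
        rat, fit = self._fit(medium_cohort)
        H = observed_information(fit, rat)
        vcov = np.linalg.pinv(H)
        traj = predict_trajectory(fit, vcov=vcov, n_draws=100, seed=1)
        assert ((traj["lo95"] <= traj["expected_rating"] + 1e-9)
                & (traj["expected_rating"] <= traj["hi95"] + 1e-9)).all()
        assert traj["expected_rating"].between(1, 4).all()
        assert traj["lo95"].between(1, 4).all() and traj["hi95"].between(1, 4).all()

    def test_missing_vcov_flags_bands_unavailable(self, medium_cohort):
        _, fit = self._fit(medium_cohort)
        traj = predict_trajectory(fit, vcov=None)
        assert not traj.attrs["bands_available"]
        assert traj["lo95"].isna().all()

    def test_saturated_latent_expected_rating_at_top(self):
        p = LCGAParams(betas=[[50.0, 0, 0, 0]], tau=[0, 1, 2])
        assert np.allclose(expected_rating(p, [0, 10, 20]), 4.0)

    def test_deterministic_per_seed(self, medium_cohort):
        rat, fit = self._fit(medium_cohort)
        H = observed_information(fit, rat)
        vcov = np.linalg.pinv(H)
        a = predict_trajectory(fit, vcov=vcov, n_draws=50, seed=5)
        b = predict_trajectory(fit, vcov=vcov, n_draws=50, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestLabelPermutationInvariance:
    def test_observables_unchanged_under_reordering(self):
        # permuting class labels then canonically reordering restores curves
        p = LCGAParams(
            betas=[[2.0, 1, 0, 0], [0.5, -1, 0, 0]], tau=[0, 1, 2], zeta=[0.3]
        )
        from tmstraj.lcga import _canonical_order, _permute_params

        perm = _permute_params(p, np.array([1, 0]))
        restored = _permute_params(perm, _canonical_order(perm))
        assert np.allclose(restored.betas, p.betas)
        assert np.allclose(restored.pi, p.pi)
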