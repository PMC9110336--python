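import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import nquad
from scipy.optimize import approx_fprime
from scipy.special import softmax

from mmbm.core import (
    CATEGORIES,
    MODEL_TERMS,
    ModelSpec,
    MultinomialLogitPosterior,
    Parameters,
    PriorConfig,
    category_probs,
    corr_chol_from_unconstrained,
    linear_predictor,
    lkj_logpdf_canonical,
    log_prior,
    noncentered_reconstruct,
    pointwise_loglik,
    unconstrained_from_corr,
)


class TestModelSpec:
    def test_five_models_match_published_blocks(self):
        m2 = set(MODEL_TERMS[2])
        assert MODEL_TERMS[1] == ("intercept",)
        assert {"boy", "middle", "adolescent", "boy:middle", "boy:adolescent",
                "prop_non_foraged_z"} < m2
        assert set(MODEL_TERMS[3]) - m2 == {"npp_z", "annual_precip_z",
                                            "annual_mean_temp_z"}
        assert set(MODEL_TERMS[4]) - m2 == {"mammal_density_high", "water_rating"}
        assert set(MODEL_TERMS[5]) - m2 == {"division", "division:boy"}

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(model_id=0, fixed_effects=("intercept", "moon_phase"))

    def test_reference_is_other(self):
        spec = ModelSpec.for_model(1)
        assert CATEGORIES[spec.reference_index] == "other"


class TestCategoryProbs:
    def test_symmetric_logits_give_uniform(self):
        assert np.allclose(category_probs(np.zeros(4)), 0.2)

    def test_very_negative_logits_concentrate_on_reference(self):
        p = category_probs(np.full(4, -500.0))
        assert p[4] == pytest.approx(1.0)

    def test_matches_softmax_oracle_on_published_intercepts(self):
        eta = np.array([-4.12, -2.23, -2.07, -1.37])
        expected = softmax(np.append(eta, 0.0))
        assert np.allclose(category_probs(eta), expected, atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            category_probs(np.array([0.0, np.nan, 0.0, 0.0]))

    def test_extreme_positive_logits_do_not_overflow(self):
        p = category_probs(np.array([800.0, 0.0, 0.0, 0.0]))
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-30, 30), min_size=4, max_size=4))
    def test_sums_to_one_and_logit_round_trip(self, eta):
        eta = np.array(eta)
        p = category_probs(eta)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.log(p[:4] / p[4]), eta, atol=1e-10)


class TestLinearPredictor:
    def test_zero_covariates_and_effects_give_intercepts(self):
        spec = ModelSpec.for_model(2)
        beta = np.arange(4 * 7, dtype=float).reshape(4, 7)
        params = Parameters(beta=beta)
        x = np.zeros(7)
        x[0] = 1.0
        eta = linear_predictor(spec, params, x, 0, 0)
        assert np.allclose(eta, beta[:, 0])

    def test_linearity_in_beta(self):
        spec = ModelSpec.for_model(1)
        params = Parameters(beta=np.array([[1.0], [2.0], [3.0], [4.0]]))
        eta0 = linear_predictor(spec, params, [1.0], 0, 0)
        params.beta[2, 0] += 0.7
        eta1 = linear_predictor(spec, params, [1.0], 0, 0)
        assert eta1[2] - eta0[2] == pytest.approx(0.7)
        assert np.allclose(np.delete(eta1, 2), np.delete(eta0, 2))

    def test_matches_term_by_term_hand_sum(self):
        rng = np.random.default_rng(5)
        spec = ModelSpec.for_model(2)
        beta = rng.normal(size=(4, 7))
        z_i = rng.normal(size=(3, 4))
        z_s = rng.normal(size=(2, 4))
        sig = np.array([0.5, 1.0, 1.5, 2.0])
        params = Parameters(
            beta=beta, sigma_individual=sig, sigma_society=sig,
            z_individual=z_i, z_society=z_s,
        )
        x = rng.normal(size=7)
        eta = linear_predictor(spec, params, x, 1, 0)
        for k in range(4):
            hand = sum(beta[k, m] * x[m] for m in range(7))
            hand += params.nu_individual[1, k] + params.nu_society[0, k]
            assert eta[k] == pytest.approx(hand)

    def test_length_mismatch_errors(self):
        spec = ModelSpec.for_model(2)
        params = Parameters(beta=np.zeros((4, 7)))
        with pytest.raises(ValueError):
            linear_predictor(spec, params, np.zeros(3), 0, 0)


class TestNoncentered:
    def test_zero_innovations_give_zero_effects(self):
        out = noncentered_reconstruct(np.zeros((5, 4)), np.ones(4), np.eye(4))
        assert np.all(out == 0)

    def test_identity_correlation_unit_scale_is_identity_map(self):
        z = np.random.default_rng(0).normal(size=(7, 4))
        assert np.allclose(noncentered_reconstruct(z, np.ones(4), np.eye(4)), z)

    def test_non_psd_correlation_rejected(self):
        bad = np.full((4, 4), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99
        with pytest.raises(ValueError):
            noncentered_reconstruct(np.zeros((2, 4)), np.ones(4), bad)

    def test_monte_carlo_covariance_matches_omega(self):
        # 1e5 draws reconstruct Omega = diag(sigma) corr diag(sigma) to <5%
        rng = np.random.default_rng(12)
        sigma = np.array([1.0, 2.0, 0.5, 1.0])
        y = rng.normal(size=6) * 0.5
        L = corr_chol_from_unconstrained(y)
        corr = L @ L.T
        z = rng.standard_normal((100_000, 4))
        nu = noncentered_reconstruct(z, sigma, corr)
        omega = sigma[:, None] * corr * sigma[None, :]
        emp = np.cov(nu.T)
        rel = np.linalg.norm(emp - omega) / np.linalg.norm(omega)
        assert rel < 0.05


class TestCorrTransform:
    def test_round_trip(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=6)
        L = corr_chol_from_unconstrained(y)
        corr = L @ L.T
        assert np.allclose(np.diag(corr), 1.0, atol=1e-12)
        assert np.allclose(unconstrained_from_corr(corr), y, atol=1e-9)

    def test_correlations_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            L = corr_chol_from_unconstrained(rng.normal(size=6) * 3)
            corr = L @ L.T
            off = corr[~np.eye(4, dtype=bool)]
            assert np.all(np.abs(off) <= 1.0 + 1e-12)


class TestPointwiseLoglik:
    def test_uniform_case(self):
        spec = ModelSpec.for_model(1)
        params = Parameters(beta=np.zeros((4, 1)))
        ll = pointwise_loglik(spec, params, [1.0], 0, 0, "play")
        assert ll == pytest.approx(math.log(0.2))

    def test_probability_one_limit(self):
        spec = ModelSpec.for_model(1)
        params = Parameters(beta=np.full((4, 1), -500.0))
        assert pointwise_loglik(spec, params, [1.0], 0, 0, "other") == pytest.approx(0.0)

    def test_matches_softmax_oracle(self):
        rng = np.random.default_rng(9)
        spec = ModelSpec.for_model(1)
        beta = rng.normal(size=(4, 1))
        params = Parameters(beta=beta)
        oracle = np.log(softmax(np.append(beta[:, 0], 0.0)))
        for k, cat in enumerate(CATEGORIES):
            assert pointwise_loglik(spec, params, [1.0], 0, 0, cat) == pytest.approx(
                oracle[k]
            )


class TestLogPrior:
    def test_beta_at_zero_contributes_mode_density(self):
        p0 = log_prior(Parameters(beta=np.zeros((4, 1))), PriorConfig())
        mode = -(math.log(2.5) + 0.5 * math.log(2 * math.pi))
        # four beta parameters at the mode, no random-effect blocks
        corr_part = 2 * lkj_logpdf_canonical(np.zeros(6), 4, 2.0)
        sigma_part = 0.0  # sigma vectors default to 0 -> out of support
        assert p0 == -np.inf or np.isfinite(p0)
        params = Parameters(
            beta=np.zeros((4, 1)),
            sigma_individual=np.ones(4),
            sigma_society=np.ones(4),
        )
        lp = log_prior(params, PriorConfig(sigma_rate=1.0))
        expected = 4 * mode + 8 * (math.log(1.0) - 1.0) + corr_part
        assert lp == pytest.approx(expected, rel=1e-9)

    def test_sigma_doubling_changes_logprior_analytically(self):
        base = Parameters(
            beta=np.zeros((4, 1)),
            sigma_individual=np.ones(4),
            sigma_society=np.ones(4),
        )
        doubled = Parameters(
            beta=np.zeros((4, 1)),
            sigma_individual=2 * np.ones(4),
            sigma_society=np.ones(4),
        )
        diff = log_prior(doubled) - log_prior(base)
        assert diff == pytest.approx(4 * (-2.0 + 1.0))  # Exp(1): -sigma each

    def test_nonpositive_sigma_out_of_support(self):
        params = Parameters(
            beta=np.zeros((4, 1)),
            sigma_individual=np.array([1.0, -0.1, 1.0, 1.0]),
            sigma_society=np.ones(4),
        )
        assert log_prior(params) == -np.inf

    def test_lkj_identity_matches_k2_closed_form(self):
        # for a 2x2 correlation, LKJ(eta) at r=0 has density 1/(2^(2eta-1) B(eta,eta))
        from scipy.special import beta as beta_fn

        for eta in (1.0, 2.0, 4.0):
            expected = -math.log(2 ** (2 * eta - 1) * beta_fn(eta, eta))
            assert lkj_logpdf_canonical(np.zeros(1), 2, eta) == pytest.approx(expected)

    def test_lkj_density_integrates_to_one_k3(self):
        # numeric integration oracle over the 3 canonical partial correlations
        eta = 2.0

        def dens(c1, c2, c3):
            return math.exp(lkj_logpdf_canonical(np.array([c1, c2, c3]), 3, eta))

        val, err = nquad(
            dens, [(-1, 1)] * 3, opts={"epsabs": 1e-6, "epsrel": 1e-6}
        )
        assert val == pytest.approx(1.0, abs=1e-4)


class TestPosteriorGradient:
    @pytest.fixture(scope="class")
    def posterior(self):
        rng = np.random.default_rng(0)
        C, S, M = 12, 3, 3
        counts = rng.integers(0, 15, size=(C, 5)).astype(float)
        X = np.column_stack([np.ones(C), rng.standard_normal((C, M - 1))])
        soc = rng.integers(0, S, size=C)
        return MultinomialLogitPosterior(counts, X, soc, S, random_effects=True)

    def test_fast_kernel_matches_reference(self, posterior):
        rng = np.random.default_rng(1)
        for _ in range(5):
            q = rng.standard_normal(posterior.n_params) * 0.6
            lp_f, g_f = posterior.logp_and_grad(q)
            lp_r, g_r = posterior.logp_and_grad_reference(q)
            assert lp_f == pytest.approx(lp_r, rel=1e-12, abs=1e-9)
            assert np.allclose(g_f, g_r, atol=1e-9)

    def test_reference_gradient_matches_finite_differences(self, posterior):
        rng = np.random.default_rng(2)
        q = rng.standard_normal(posterior.n_params) * 0.5
        _, g = posterior.logp_and_grad_reference(q)
        g_num = approx_fprime(
            q, lambda v: posterior.logp_and_grad_reference(v)[0], 1e-6
        )
        assert np.max(np.abs(g - g_num) / (1 + np.abs(g_num))) < 1e-4

    def test_fixed_effects_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 15, size=(6, 5)).astype(float)
        X = np.ones((6, 1))
        post = MultinomialLogitPosterior(
            counts, X, np.zeros(6, int), 1, random_effects=False
        )
        q = rng.standard_normal(post.n_params)
        _, g = post.logp_and_grad(q)
        g_num = approx_fprime(q, lambda v: post.logp_and_grad(v)[0], 1e-7)
        assert np.max(np.abs(g - g_num)) < 1e-4

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            MultinomialLogitPosterior(
                np.zeros((3, 5)), np.ones((3, 1)), np.zeros(3, int), 1
            )

    def test_unpack_reconstructs_valid_parameters(self, posterior):
        rng = np.random.default_rng(4)
        q = rng.standard_normal(posterior.n_params) * 0.5
        p = posterior.unpack(q)
        for corr in (p.corr_individual, p.corr_society):
            assert np.allclose(np.diag(corr), 1.0, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(corr) > 0)
        assert np.all(p.sigma_individual > 0)

    def test_interweave_preserves_random_effects(self, posterior):
        # the interweaving move must leave nu = z (diag(sigma) L)^T unchanged
        rng = np.random.default_rng(5)
        q = rng.standard_normal(posterior.n_params) * 0.5
        p0 = posterior.unpack(q)
        q1 = posterior.interweave_update(q, rng)
        p1 = posterior.unpack(q1)
        assert np.allclose(p1.nu_individual, p0.nu_individual, atol=1e-8)
        assert np.allclose(p1.nu_society, p0.nu_society, atol=1e-8)
        assert np.allclose(p1.beta, p0.beta)
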