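"""Posterior computation: likelihood, marginals, ordering posteriors, estimates."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from pocrm_bma import (
    InvalidParameterError,
    PartialOrderSpec,
    SimpleOrdering,
    Skeleton,
    TrialData,
    WorkingModelConfig,
    bma_point_estimates,
    compute_tables,
    log_likelihood,
    marginal_likelihood,
    mixture_cdf,
    mixture_density,
    mixture_summaries,
    pocrm_point_estimates,
    posterior_mean_a,
    posterior_ordering_probs,
    select_ordering,
)
from pocrm_bma.inference import prior_log_density

from conftest import random_counts

# ordering posteriors of the worked example, as published
P_COHORT_11 = (0.1568, 0.1497, 0.1878, 0.1568, 0.1582, 0.1906)
P_COHORT_12 = (0.1743, 0.1091, 0.1840, 0.1743, 0.1840, 0.1743)


class TestLogLikelihood:
    def test_empty_trial_is_zero(self, ex):
        data = TrialData.empty(6)
        assert log_likelihood(0.7, data, ex.skeleton.values, ex.model) == 0.0

    def test_closed_form_at_prior_mean(self, ex):
        # at a = 0 the exponent is exp(0) = 1, so psi equals the skeleton
        data = ex.data_cohort11
        alpha = ex.skeleton.values
        expected = np.sum(
            data.y_arr * np.log(alpha) + (data.n_arr - data.y_arr) * np.log1p(-alpha)
        )
        assert log_likelihood(0.0, data, alpha, ex.model) == pytest.approx(expected, rel=1e-12)

    def test_single_binomial_term(self):
        config = WorkingModelConfig()
        data = TrialData.from_counts([2], [1])
        # a = 0 leaves the skeleton untouched: psi = 0.3
        got = log_likelihood(0.0, data, [0.3], config)
        assert got == pytest.approx(np.log(0.3 * 0.7), rel=1e-12)

    def test_extreme_parameter_stays_finite(self, ex):
        for a in (-50.0, 50.0):
            assert np.isfinite(log_likelihood(a, ex.data_cohort12, ex.skeleton.values, ex.model))


class TestMarginalLikelihood:
    def test_empty_trial_gives_one(self, ex):
        data = TrialData.empty(6)
        for m in range(1, 7):
            assert marginal_likelihood(m, data, ex.spec, ex.skeleton, ex.model) == pytest.approx(1.0, abs=1e-9)

    def test_orderings_agreeing_on_observed_doses_tie(self, ex):
        # after cohort 12 the by-rows ordering (m=1) and m=6 differ only in the
        # ranks of doses 2 and 3, which carry identical data -> equal marginals
        t = compute_tables(ex.data_cohort12, ex.spec, ex.skeleton, ex.model)
        assert t.log_marginal[0] == pytest.approx(t.log_marginal[5], abs=1e-9)
        assert t.log_marginal[2] == pytest.approx(t.log_marginal[4], abs=1e-9)

    def test_matches_adaptive_quadrature(self, ex):
        data = ex.data_cohort11
        alpha = ex.skeleton.values  # m=1 permutation is the identity
        sd = ex.model.prior_sd

        def integrand(a):
            return np.exp(log_likelihood(a, data, alpha, ex.model)) * norm.pdf(a, scale=sd)

        oracle, _ = quad(integrand, -14, 14, limit=200, epsabs=1e-13)
        got = marginal_likelihood(1, data, ex.spec, ex.skeleton, ex.model)
        assert got == pytest.approx(oracle, rel=1e-10)


class TestOrderingPosteriors:
    def test_empty_trial_returns_prior(self, ex):
        p = posterior_ordering_probs(TrialData.empty(6), ex.spec, ex.skeleton, ex.model)
        assert np.allclose(p, 1 / 6, atol=1e-12)

    def test_published_cohort_11_row(self, ex):
        p = posterior_ordering_probs(ex.data_cohort11, ex.spec, ex.skeleton, ex.model)
        assert np.allclose(p, P_COHORT_11, atol=5e-4)

    def test_published_cohort_12_row(self, ex):
        p = posterior_ordering_probs(ex.data_cohort12, ex.spec, ex.skeleton, ex.model)
        assert np.allclose(p, P_COHORT_12, atol=5e-4)

    def test_sums_to_one_and_patient_order_irrelevant(self, ex):
        rng = np.random.default_rng(4)
        pairs = [(2, 0), (4, 1), (4, 0), (1, 0), (5, 1), (4, 0), (6, 1)]
        p_ref = None
        for _ in range(5):
            rng.shuffle(pairs)
            data = TrialData.from_history(6, pairs)
            p = posterior_ordering_probs(data, ex.spec, ex.skeleton, ex.model)
            assert p.sum() == pytest.approx(1.0, abs=1e-10)
            if p_ref is None:
                p_ref = p
            assert np.allclose(p, p_ref, atol=1e-12)


class TestPosteriorMeanA:
    def test_empty_trial_returns_prior_mean(self, ex):
        assert posterior_mean_a(1, TrialData.empty(6), ex.spec, ex.skeleton, ex.model) == pytest.approx(0.0, abs=1e-9)

    def test_brute_force_trapezoid_oracle(self, ex):
        data = ex.data_cohort11
        t = compute_tables(data, ex.spec, ex.skeleton, ex.model)
        a = np.linspace(-10, 10, 10001)
        for m in (6, 2):
            ll = log_likelihood(a, data, t.alpha[m - 1], ex.model)
            dens = np.exp(ll) * norm.pdf(a, scale=ex.model.prior_sd)
            oracle = np.trapezoid(a * dens, a) / np.trapezoid(dens, a)
            got = posterior_mean_a(m, data, ex.spec, ex.skeleton, ex.model)
            assert got == pytest.approx(oracle, abs=1e-6)


class TestPocrmEstimates:
    def test_cohort_11_selects_the_max_posterior_ordering(self, ex):
        m, _ = pocrm_point_estimates(ex.data_cohort11, ex.spec, ex.skeleton, ex.model)
        assert m == 6

    def test_cohort_12_dose4_estimate_and_change(self, ex):
        _, e11 = pocrm_point_estimates(ex.data_cohort11, ex.spec, ex.skeleton, ex.model)
        _, e12 = pocrm_point_estimates(ex.data_cohort12, ex.spec, ex.skeleton, ex.model)
        assert e11[3] == pytest.approx(0.49, abs=5e-3)
        assert e12[3] == pytest.approx(0.56, abs=5e-3)
        assert e12[3] - e11[3] == pytest.approx(0.07, abs=1e-2)

    def test_cohort_12_dose2_dose5_changes(self, ex):
        _, e11 = pocrm_point_estimates(ex.data_cohort11, ex.spec, ex.skeleton, ex.model)
        _, e12 = pocrm_point_estimates(ex.data_cohort12, ex.spec, ex.skeleton, ex.model)
        assert e12[1] - e11[1] == pytest.approx(-0.2147, abs=1e-2)
        assert e12[4] - e11[4] == pytest.approx(-0.2259, abs=1e-2)

    def test_tie_break_rules_are_deterministic(self):
        post = np.array([0.2, 0.3, 0.3, 0.2])
        assert select_ordering(post, "highest") == 3
        assert select_ordering(post, "lowest") == 2
        with pytest.raises(InvalidParameterError):
            select_ordering(post, "random")

    def test_estimates_ordered_like_the_selected_permutation(self, ex):
        rng = np.random.default_rng(11)
        for _ in range(20):
            data = random_counts(rng, 6)
            m, est = pocrm_point_estimates(data, ex.spec, ex.skeleton, ex.model)
            ranks = ex.spec.orderings[m - 1].ranks
            assert np.all(np.diff(est[np.argsort(ranks)]) > 0)

    def test_dlt_never_lowers_estimate_at_administered_dose(self, ex):
        rng = np.random.default_rng(12)
        single = PartialOrderSpec.uniform([SimpleOrdering((1, 2, 3, 4, 5, 6))])
        for _ in range(30):
            data = random_counts(rng, 6)
            dose = int(rng.integers(1, 7))
            _, before = pocrm_point_estimates(data, single, ex.skeleton, ex.model)
            _, after = pocrm_point_estimates(
                data.with_outcome(dose, 1), single, ex.skeleton, ex.model
            )
            assert after[dose - 1] >= before[dose - 1] - 1e-12


class TestBmaEstimates:
    def test_cohort_12_changes(self, ex):
        b11 = bma_point_estimates(ex.data_cohort11, ex.spec, ex.skeleton, ex.model)
        b12 = bma_point_estimates(ex.data_cohort12, ex.spec, ex.skeleton, ex.model)
        assert b12[1] - b11[1] == pytest.approx(-0.039, abs=1e-2)
        assert b12[4] - b11[4] == pytest.approx(-0.0159, abs=1e-2)

    def test_coherent_case_no_rise_in_comparable_sets(self, ex, ex_sets):
        # cohort 12 is a non-DLT at dose 2: no comparable dose's estimate rises
        b11 = bma_point_estimates(ex.data_cohort11, ex.spec, ex.skeleton, ex.model)
        b12 = bma_point_estimates(ex.data_cohort12, ex.spec, ex.skeleton, ex.model)
        for j in ex_sets.combined(2):
            assert b12[j - 1] <= b11[j - 1] + 1e-9

    def test_single_ordering_reduces_to_model_selection_ranks(self, ex):
        single = PartialOrderSpec.uniform([SimpleOrdering((1, 2, 3, 4, 5, 6))])
        data = ex.data_cohort11
        bma = bma_point_estimates(data, single, ex.skeleton, ex.model)
        t = compute_tables(data, single, ex.skeleton, ex.model)
        # with one ordering the averaged estimate is that ordering's posterior mean
        assert np.allclose(bma, t.est[0], atol=1e-14)


class TestMixtureDensity:
    def test_boundary_rejected(self, ex):
        with pytest.raises(InvalidParameterError):
            mixture_density(ex.data_cohort12, ex.spec, ex.skeleton, ex.model, 4, 0.0)

    def test_integrates_to_one(self, ex, rspace_rule):
        r, wt = rspace_rule
        rng = np.random.default_rng(21)
        for _ in range(3):
            # a DLT and a non-DLT at every dose pins both tails of the risk posterior
            n = rng.integers(2, 5, 6)
            y = np.array([1 + rng.integers(0, nk - 1) for nk in n])
            data = TrialData.from_counts(n, y)
            for dose in (1, 4, 6):
                g = mixture_density(data, ex.spec, ex.skeleton, ex.model, dose, r)
                assert np.sum(wt * g) == pytest.approx(1.0, abs=1e-6)

    def test_mean_matches_point_estimates(self, ex, rspace_rule):
        r, wt = rspace_rule
        bma = bma_point_estimates(ex.data_cohort12, ex.spec, ex.skeleton, ex.model)
        for dose in (2, 4):
            g = mixture_density(ex.data_cohort12, ex.spec, ex.skeleton, ex.model, dose, r)
            assert np.sum(wt * r * g) == pytest.approx(bma[dose - 1], abs=1e-8)

    def test_single_ordering_equals_transformed_posterior(self, ex):
        single = PartialOrderSpec.uniform([SimpleOrdering((1, 2, 3, 4, 5, 6))])
        data = ex.data_cohort11
        t = compute_tables(data, single, ex.skeleton, ex.model)
        r = np.array([0.2, 0.4, 0.6])
        dose = 4
        alpha_k = t.alpha[0, dose - 1]
        a_of_r = ex.model.inverse(alpha_k, r)
        ll = log_likelihood(a_of_r, data, t.alpha[0], ex.model)
        f = np.exp(ll + prior_log_density(a_of_r, ex.model) - t.log_marginal[0])
        expected = f * ex.model.dinverse_dr(alpha_k, r)
        got = mixture_density(data, single, ex.skeleton, ex.model, dose, r)
        assert np.allclose(got, expected, rtol=1e-12)


class TestMixtureSummaries:
    def test_overdose_probability_boundaries(self, ex):
        s0 = mixture_summaries(ex.data_cohort12, ex.spec, ex.skeleton, ex.model, 4, theta=0.0)
        s1 = mixture_summaries(ex.data_cohort12, ex.spec, ex.skeleton, ex.model, 4, theta=1.0)
        assert s0.overdose_prob == 1.0
        assert s1.overdose_prob == 0.0

    def test_prior_interval_is_transformed_normal_quantiles(self, ex):
        # no data, single ordering: the risk quantiles are the (monotone
        # decreasing) transform of the parameter's Normal prior quantiles
        single = PartialOrderSpec.uniform([SimpleOrdering((1, 2, 3, 4, 5, 6))])
        data = TrialData.empty(6)
        dose, level = 3, 0.9
        s = mixture_summaries(data, single, ex.skeleton, ex.model, dose, level=level)
        sd = ex.model.prior_sd
        alpha_k = ex.skeleton.values[dose - 1]
        hi_a = norm.ppf(1 - (1 - level) / 2, scale=sd)
        lo_a = norm.ppf((1 - level) / 2, scale=sd)
        assert s.lower == pytest.approx(float(ex.model.psi(alpha_k, np.asarray(hi_a))), abs=1e-5)
        assert s.upper == pytest.approx(float(ex.model.psi(alpha_k, np.asarray(lo_a))), abs=1e-5)

    def test_cdf_against_monte_carlo(self, ex):
        # sample the mixture: ordering by posterior weight, then the parameter
        # by inverse-CDF on a fine grid, pushed through the working model
        from pocrm_bma.inference import _rule

        data = ex.data_cohort12
        t = compute_tables(data, ex.spec, ex.skeleton, ex.model)
        a, wt, logp, _, _ = _rule("power_exp", 0.0, ex.model.prior_sd)
        rng = np.random.default_rng(17)
        dose = 4
        n_mc = 100_000
        ms = rng.choice(t.M, size=n_mc, p=t.ordering_post)
        draws = []
        for m in range(t.M):
            cnt = int((ms == m).sum())
            ll = log_likelihood(a, data, t.alpha[m], ex.model)
            dens = np.exp(ll + logp - t.log_marginal[m]) * wt
            cdf = np.cumsum(dens)
            cdf /= cdf[-1]
            idx = np.searchsorted(cdf, rng.random(cnt))
            draws.append(ex.model.psi(t.alpha[m, dose - 1], a[np.clip(idx, 0, a.size - 1)]))
        draws = np.concatenate(draws)
        for q in (0.3, 0.5, 0.7):
            mc = float((draws <= q).mean())
            assert mixture_cdf(data, ex.spec, ex.skeleton, ex.model, dose, q) == pytest.approx(mc, abs=5e-3)
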