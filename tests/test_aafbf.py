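"""Fit, complexity and Bayes factors: closed forms, oracles and invariances."""

import math

import numpy as np
import pytest
from scipy import stats

from ssdanova import (
    GroupSummaries,
    NormalApprox,
    approximate_distributions,
    bayes_factor,
    build_pair,
    fit_or_complexity,
    format_b,
    fraction_b,
    parse_hypothesis,
)
from ssdanova.aafbf import bf_batch, bvn_cdf, fit_complexity_batch


def _summaries(centers, obs_variances, N, method="ml_pooled"):
    return GroupSummaries(
        np.asarray(centers, float), np.asarray(obs_variances, float), N, method
    )


class TestFractionB:
    @pytest.mark.parametrize(
        "J,K,N,m,value,printed",
        [
            (2, 3, 73, 1, 2 / 219, "0.009"),
            (2, 3, 62, 2, 4 / 186, "0.021"),
            (2, 3, 55, 3, 6 / 165, "0.036"),
            (2, 3, 50, 1, 2 / 150, "0.013"),
            (1, 1, 1, 1, 1.0, "1.000"),
        ],
    )
    def test_values_and_floored_formatting(self, J, K, N, m, value, printed):
        b = fraction_b(J, K, N, m)
        assert b == pytest.approx(value, rel=1e-12)
        assert format_b(b) == printed

    def test_formatting_truncates_not_rounds(self):
        # 2/114 = 0.01754 must print 0.017, and 4/186 = 0.02151 prints 0.021
        assert format_b(2 / 114) == "0.017"
        assert format_b(0.0199) == "0.019"

    def test_fraction_exceeding_one_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            fraction_b(3, 2, 1, 1)


class TestApproximateDistributions:
    def test_posterior_and_prior_variances(self):
        s = _summaries([550, 560, 580], [2500] * 3, 73)
        b = fraction_b(2, 3, 73)
        post, prior = approximate_distributions(s, b)
        np.testing.assert_allclose(post.variances, 2500 / 73)
        # with b = J/(K N) the prior variance collapses to K s^2 / J
        np.testing.assert_allclose(prior.variances, 3 * 2500 / 2)
        np.testing.assert_allclose(prior.mean, 0.0)

    def test_b_equal_one_makes_prior_match_posterior_scale(self):
        s = _summaries([1.0, 2.0], [4.0, 9.0], 20, "ml_groupwise")
        post, prior = approximate_distributions(s, 1.0)
        np.testing.assert_allclose(prior.variances, post.variances)

    def test_groupwise_variances_keep_their_order(self):
        s = _summaries([0, 0, 0], [1.0, 2.0, 3.0], 10, "ml_groupwise")
        post, _ = approximate_distributions(s, 0.5)
        np.testing.assert_allclose(post.variances, np.array([1, 2, 3]) / 10)


class TestBivariateNormal:
    def test_against_scipy_on_grid(self, rng):
        for _ in range(100):
            h, k = rng.normal(size=2) * 2
            rho = rng.uniform(-0.99, 0.99)
            ref = stats.multivariate_normal.cdf([h, k], mean=[0, 0], cov=[[1, rho], [rho, 1]])
            assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("h,k,rho", [(0, 0, -0.5), (0, 1.3, 0.4), (-0.7, 0, 0.2), (0, 0, 0.9)])
    def test_zero_edges_match_scipy(self, h, k, rho):
        ref = stats.multivariate_normal.cdf([h, k], mean=[0, 0], cov=[[1, rho], [rho, 1]])
        assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=1e-10)


class TestFitOrComplexity:
    def test_full_ordering_complexity_is_one_over_k_factorial(self, ordered_k3):
        c = fit_or_complexity(ordered_k3, NormalApprox(np.zeros(3), np.ones(3)))
        assert c.probability_part == pytest.approx(1 / 6, abs=1e-12)
        assert c.density_part == 1.0

    def test_null_density_on_two_groups_closed_form(self):
        h0 = parse_hypothesis("mu1=mu2", 2)
        fc = fit_or_complexity(h0, NormalApprox(np.zeros(2), np.ones(2)))
        assert fc.value == pytest.approx(1 / math.sqrt(4 * math.pi), abs=1e-12)

    def test_single_inequality_closed_form(self):
        h = parse_hypothesis("mu1>mu2", 2)
        fc = fit_or_complexity(h, NormalApprox(np.array([0.5, 0.0]), np.array([0.25, 0.25])))
        assert fc.probability_part == pytest.approx(stats.norm.cdf(0.5 / math.sqrt(0.5)), abs=1e-12)

    def test_unconstrained_alternative_is_unit(self, ha_k3):
        fc = fit_or_complexity(ha_k3, NormalApprox(np.zeros(3), np.ones(3)))
        assert fc.value == 1.0

    def test_three_inequalities_use_monte_carlo_with_se(self):
        h = parse_hypothesis("mu1>mu2>mu3>mu4", 4)
        fc = fit_or_complexity(
            h, NormalApprox(np.zeros(4), np.ones(4)), mc_draws=2**16,
            rng=np.random.default_rng(5),
        )
        assert fc.mc_se > 0
        assert fc.probability_part == pytest.approx(1 / 24, abs=4 * fc.mc_se + 1e-3)

    def test_mixed_chain_conditions_inequality_on_equality(self):
        # mu1 > mu2 = mu3 with independent unit variances: given mu2 = mu3,
        # mu1 - (mu2+mu3)/2 ~ N(m1 - (m2+m3)/2, 1 + 1/2)
        h = parse_hypothesis("mu1>mu2=mu3", 3)
        mean = np.array([1.0, 0.2, 0.2])
        fc = fit_or_complexity(h, NormalApprox(mean, np.ones(3)))
        expected = stats.norm.cdf(0.8 / math.sqrt(1.5))
        assert fc.probability_part == pytest.approx(expected, abs=1e-10)

    def test_redundant_equalities_raise(self):
        h = parse_hypothesis("mu1=mu2", 2)
        bad = type(h)(
            label="dup", kind="constrained", K=2,
            equality_rows=((1, -1), (1, -1)), inequality_rows=(),
        )
        with pytest.raises(np.linalg.LinAlgError):
            fit_or_complexity(bad, NormalApprox(np.zeros(2), np.ones(2)))


class TestBayesFactor:
    def test_identical_hypotheses_give_unit_bf(self, ordered_k3):
        pair = build_pair(ordered_k3, ordered_k3)
        s = _summaries([1.0, 2.0, 3.0], [1.0] * 3, 20)
        res = bayes_factor(pair, s, b=0.1)
        assert res.bf_12 == pytest.approx(1.0, abs=1e-12)

    def test_savage_dickey_closed_form_on_equal_means(self):
        # equality-only hypothesis at zero observed difference: BF_0a = 1/sqrt(b)
        pair = build_pair(parse_hypothesis("mu1=mu2", 2), parse_hypothesis("Ha", 2))
        for b in (0.04, 0.2, 0.5):
            s = _summaries([3.0, 3.0], [2.0, 2.0], 25)
            res = bayes_factor(pair, s, b=b)
            assert res.bf_12 == pytest.approx(1 / math.sqrt(b), abs=1e-10)

    def test_complement_closed_form(self):
        # P(mu1 > mu2) = Phi(0.5/sqrt(0.5)) = 0.76025; complexity 1/2 by symmetry
        pair = build_pair(parse_hypothesis("mu1>mu2", 2), parse_hypothesis("Hc", 2))
        s = _summaries([0.5, 0.0], [2.5, 2.5], 10)
        res = bayes_factor(pair, s, b=0.37)
        f = stats.norm.cdf(0.5 / math.sqrt(0.5))
        assert res.bf_12 == pytest.approx((f / 0.5) / ((1 - f) / 0.5), abs=1e-9)
        assert res.bf_12 == pytest.approx(3.1710, abs=2e-4)

    def test_bf12_times_bf21_is_one(self, rng):
        h1 = parse_hypothesis("mu1>mu2>mu3", 3)
        h2 = parse_hypothesis("mu2>mu3>mu1", 3)
        pair = build_pair(h1, h2)
        for _ in range(10):
            s = _summaries(rng.normal(size=3), rng.uniform(0.5, 2.0, size=3), 15, "ml_groupwise")
            res = bayes_factor(pair, s, b=0.05)
            assert res.bf_12 * res.bf_21 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("hyp2", ["Hc", "mu3>mu2>mu1"])
    def test_inequality_only_bfs_invariant_to_prior_multiplier(self, hyp2, rng):
        # situations 3 and 4 carry no equality constraints, so rescaling the
        # zero-centred prior leaves the cone probabilities unchanged
        h1 = parse_hypothesis("mu1>mu2>mu3", 3)
        pair = build_pair(h1, parse_hypothesis(hyp2, 3))
        s = _summaries(rng.normal(size=3), rng.uniform(0.5, 2.0, size=3), 40, "ml_groupwise")
        values = [
            bayes_factor(pair, s, b=fraction_b(pair.J, 3, 40, m)).bf_12 for m in (1, 2, 3)
        ]
        assert values[0] == pytest.approx(values[1], rel=1e-10)
        assert values[0] == pytest.approx(values[2], rel=1e-10)

    def test_situation_2_bf_is_density_over_order_ratio(self):
        pair = build_pair(
            parse_hypothesis("mu1=mu2=mu3", 3), parse_hypothesis("mu3>mu2>mu1", 3)
        )
        s = _summaries([1.0, 2.0, 3.0], [4.0] * 3, 30)
        res = bayes_factor(pair, s, b=fraction_b(2, 3, 30))
        assert res.bf_12 > 0
        assert res.bf_12 == pytest.approx(
            (res.fit1.value / res.comp1.value) / (res.fit2.value / res.comp2.value)
        )

    def test_vanishing_fit_flags_infinite_bf(self):
        # posterior mass of the reversed ordering is numerically zero
        pair = build_pair(
            parse_hypothesis("mu1>mu2>mu3", 3), parse_hypothesis("mu3>mu2>mu1", 3)
        )
        s = _summaries([30.0, 0.0, -30.0], [1.0] * 3, 100)
        res = bayes_factor(pair, s, b=0.01)
        assert res.infinite and math.isinf(res.bf_12)

    def test_complexity_one_over_factorial_up_to_k5(self, rng):
        for K in (3, 4, 5):
            text = ">".join(f"mu{i}" for i in range(1, K + 1))
            h = parse_hypothesis(text, K)
            fc = fit_or_complexity(
                h, NormalApprox(np.zeros(K), np.ones(K)), mc_draws=2**17,
                rng=np.random.default_rng(K),
            )
            tol = 3 * fc.mc_se if fc.mc_se else 1e-10
            assert fc.probability_part == pytest.approx(
                1 / math.factorial(K), abs=max(tol, 2e-3)
            )


class TestBatchConsistency:
    def test_batch_matches_scalar_path(self, rng):
        h = parse_hypothesis("mu1>mu2=mu3", 3)
        means = rng.normal(size=(50, 3))
        variances = rng.uniform(0.5, 2.0, size=(50, 3))
        dens, prob = fit_complexity_batch(h, means, variances)
        for i in (0, 17, 49):
            fc = fit_or_complexity(h, NormalApprox(means[i], variances[i]))
            assert dens[i] == pytest.approx(fc.density_part, rel=1e-12)
            assert prob[i] == pytest.approx(fc.probability_part, rel=1e-12)

    def test_bf_batch_matches_bayes_factor(self, rng):
        pair = build_pair(
            parse_hypothesis("mu1=mu2=mu3", 3), parse_hypothesis("mu3>mu2>mu1", 3)
        )
        N, b = 25, fraction_b(2, 3, 25)
        centers = rng.normal(size=(20, 3))
        obsvar = rng.uniform(0.5, 2.0, size=(20, 3))
        bfs = bf_batch(pair, centers, obsvar, N, b)
        for i in (0, 9, 19):
            s = _summaries(centers[i], obsvar[i], N, "ml_groupwise")
            assert bfs[i] == pytest.approx(bayes_factor(pair, s, b).bf_12, rel=1e-10)

    def test_median_bf_supports_truth_as_n_grows(self, rng):
        # consistency direction: under H0 the null BF grows with N, under an
        # ordering the ordered BF grows
        from ssdanova.estimators import batch_summaries

        pair = build_pair(
            parse_hypothesis("mu1=mu2=mu3", 3), parse_hypothesis("mu3>mu2>mu1", 3)
        )
        med_h0, med_h1 = [], []
        for N in (20, 80, 320):
            y0 = rng.normal(size=(400, N, 3))
            c0, v0 = batch_summaries(y0, "equal")
            med_h0.append(np.median(bf_batch(pair, c0, v0, N, fraction_b(2, 3, N))))
            y1 = rng.normal(size=(400, N, 3)) + np.array([0.0, 0.3, 0.6])
            c1, v1 = batch_summaries(y1, "equal")
            med_h1.append(np.median(1 / bf_batch(pair, c1, v1, N, fraction_b(2, 3, N))))
        assert med_h0[0] < med_h0[1] < med_h0[2]
        assert med_h1[0] < med_h1[1] < med_h1[2]
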