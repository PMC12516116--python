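"""Reference statistics: LR, summed-score, M2, information criteria."""

from itertools import product

import numpy as np
import pytest

from ghtirt.estimators import SNPIRT2PL
from ghtirt.gof import (
    information_criteria,
    lr_test,
    m2_test,
    summed_score_distribution,
    xbar2_test,
)
from ghtirt.likelihood import gauss_hermite_rule, snp_full_loglik
from ghtirt.snp import SNPShape

RULE = gauss_hermite_rule(49)


@pytest.fixture(scope="module")
def ml_fit(toy_data):
    return SNPIRT2PL(L=0).fit(toy_data)


class TestLRTest:
    def test_nested_fits_give_nonnegative_statistic(self, toy_data, ml_fit):
        fit1 = SNPIRT2PL(L=1, item_starts=ml_fit.theta_).fit(toy_data)
        res = lr_test(fit1, ml_fit)
        assert res.name == "LR1"
        assert res.statistic >= 0
        assert res.dof == 1

    def test_identical_logliks_give_zero_and_p_one(self, toy_data, ml_fit):
        fit1 = SNPIRT2PL(L=1, item_starts=ml_fit.theta_).fit(toy_data)
        fit1.loglik_ = ml_fit.loglik_  # force an exactly tied comparison
        res = lr_test(fit1, ml_fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_equal_degrees_rejected(self, ml_fit):
        with pytest.raises(ValueError):
            lr_test(ml_fit, ml_fit)

    def test_badly_ordered_logliks_raise(self, toy_data, ml_fit):
        worse = SNPIRT2PL(L=1).fit(toy_data)
        worse.loglik_ = ml_fit.loglik_ - 5.0  # simulate an under-optimized fit
        with pytest.raises(FloatingPointError):
            lr_test(worse, ml_fit)

    def test_pl_fit_rejected(self, toy_data, ml_fit):
        from ghtirt.estimators import PairwiseIRT2PL
        with pytest.raises(ValueError):
            lr_test(ml_fit, PairwiseIRT2PL().fit(toy_data))


class TestSummedScoreDistribution:
    def test_two_fair_coins(self):
        probs = summed_score_distribution([0, 0], [0, 0], SNPShape(0), RULE)
        np.testing.assert_allclose(probs, [0.25, 0.5, 0.25], atol=1e-12)

    def test_matches_pattern_enumeration(self):
        rng = np.random.default_rng(23)
        a0 = rng.uniform(-0.8, 1.12, 5)
        a1 = rng.uniform(0.5, 1.5, 5)
        shape = SNPShape(1, (0.6,))
        probs = summed_score_distribution(a0, a1, shape, RULE)
        patterns = np.array(list(product((0, 1), repeat=5)), dtype=float)
        pattern_probs = np.exp(snp_full_loglik(patterns, a0, a1, shape, RULE))
        brute = np.bincount(patterns.sum(axis=1).astype(int), weights=pattern_probs)
        np.testing.assert_allclose(probs, brute, atol=1e-10)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_item_order(self):
        rng = np.random.default_rng(29)
        a0 = rng.uniform(-0.8, 1.12, 6)
        a1 = rng.uniform(0.5, 1.5, 6)
        forward = summed_score_distribution(a0, a1, SNPShape(0), RULE)
        backward = summed_score_distribution(a0[::-1], a1[::-1], SNPShape(0), RULE)
        np.testing.assert_allclose(forward, backward, atol=1e-12)


class TestXbar2:
    def test_dof_is_items_minus_two(self, toy_data, ml_fit):
        res = xbar2_test(toy_data, ml_fit)
        assert res.dof == toy_data.shape[1] - 2
        assert res.statistic >= 0

    def test_too_few_items_rejected(self, ml_fit):
        with pytest.raises(ValueError):
            xbar2_test(np.zeros((20, 2)), ml_fit)

    def test_perfect_fit_gives_zero_statistic(self, ml_fit, toy_data):
        """Build a pseudo-sample whose score proportions equal the
        model-implied ones; the statistic must vanish."""
        implied = summed_score_distribution(ml_fit.intercepts_raw_, ml_fit.slopes_raw_,
                                            ml_fit.shape_, ml_fit._rule())
        counts = np.round(implied * 40000).astype(int)
        rows = []
        for s, c in enumerate(counts):
            row = np.zeros(5)
            row[:s] = 1.0
            rows += [row] * c
        X = np.array(rows)
        res = xbar2_test(X, ml_fit)
        assert res.statistic == pytest.approx(0.0, abs=0.05)  # rounding of counts

    def test_invariant_to_person_order(self, toy_data, ml_fit):
        perm = np.random.default_rng(0).permutation(toy_data.shape[0])
        a = xbar2_test(toy_data, ml_fit)
        b = xbar2_test(toy_data[perm], ml_fit)
        assert a.statistic == b.statistic


class TestM2:
    def test_dof_formula(self, toy_data, ml_fit):
        res = m2_test(toy_data, ml_fit)
        p = toy_data.shape[1]
        assert res.dof == p * (p + 1) / 2 - 2 * p

    def test_matches_full_pattern_transcription(self, toy_data, ml_fit):
        """Dense oracle: margins, their multinomial covariance and Jacobian
        all built from exhaustive 2^p pattern probabilities."""
        Y = toy_data
        n, p = Y.shape
        patterns = np.array(list(product((0, 1), repeat=p)), dtype=float)

        def pattern_probs(theta):
            return np.exp(snp_full_loglik(patterns, theta[:p], theta[p:], SNPShape(0),
                                          ml_fit._rule()))

        pi = pattern_probs(ml_fit.theta_)
        # margin operator: all univariate then bivariate (j < k)
        T = [patterns[:, j] for j in range(p)]
        T += [patterns[:, j] * patterns[:, k] for j in range(p) for k in range(j + 1, p)]
        T = np.array(T)
        # observed pattern proportions
        idx = (Y @ (2 ** np.arange(p - 1, -1, -1))).astype(int)
        pobs = np.bincount(idx, minlength=2**p) / n
        e2 = T @ (pobs - pi)
        Xi = T @ np.diag(pi) @ T.T - np.outer(T @ pi, T @ pi)
        Delta = np.empty((T.shape[0], 2 * p))
        for i in range(2 * p):
            e = np.zeros(2 * p)
            e[i] = 1e-6
            Delta[:, i] = T @ (pattern_probs(ml_fit.theta_ + e)
                               - pattern_probs(ml_fit.theta_ - e)) / 2e-6
        Xi_inv = np.linalg.inv(Xi)
        U2 = Xi_inv - Xi_inv @ Delta @ np.linalg.solve(
            Delta.T @ Xi_inv @ Delta, Delta.T @ Xi_inv)
        oracle = n * e2 @ U2 @ e2
        res = m2_test(Y, ml_fit)
        assert res.statistic == pytest.approx(oracle, rel=1e-5)

    def test_invariant_to_person_order(self, toy_data, ml_fit):
        perm = np.random.default_rng(1).permutation(toy_data.shape[0])
        a = m2_test(toy_data, ml_fit)
        b = m2_test(toy_data[perm], ml_fit)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_null_statistic_near_dof(self, toy_bank):
        """Data simulated exactly from the fitted model: the statistic's
        mean should sit near its dof (a light 30-replication check)."""
        from ghtirt.simulate import generate_responses, sample_latent, SCENARIOS
        a0, a1 = toy_bank
        stats = []
        root = np.random.SeedSequence(555)
        for sd in root.spawn(30):
            s1, s2 = sd.spawn(2)
            z = sample_latent(SCENARIOS["A"], 600, s1)
            Y = generate_responses(a0, a1, z, s2)
            fit = SNPIRT2PL(L=0).fit(Y)
            stats.append(m2_test(Y, fit).statistic)
        m = 5 * 6 / 2 - 10
        assert abs(np.mean(stats) - m) < 3 * np.sqrt(2 * m / 30)


class TestInformationCriteria:
    def test_arithmetic(self, ml_fit):
        ic = information_criteria(ml_fit)
        assert ic.k == 2 * ml_fit.n_features_in_
        assert ic.aic == pytest.approx(-2 * ml_fit.loglik_ + 2 * ic.k)
        assert ic.bic - ic.aic == pytest.approx(ic.k * (np.log(ic.n) - 2))
        assert ic.hq == pytest.approx(-2 * ml_fit.loglik_
                                      + 2 * ic.k * np.log(np.log(ic.n)))

    def test_snp1_has_one_more_parameter(self, toy_data, ml_fit):
        fit1 = SNPIRT2PL(L=1, item_starts=ml_fit.theta_).fit(toy_data)
        assert information_criteria(fit1).k == information_criteria(ml_fit).k + 1

    def test_pl_fit_rejected(self, toy_data):
        from ghtirt.estimators import PairwiseIRT2PL
        with pytest.raises(ValueError):
            information_criteria(PairwiseIRT2PL().fit(toy_data))
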