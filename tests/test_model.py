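import numpy as np
import pytest
from scipy import integrate, special

from ibbpair import (
    FeaturePairSet,
    IbbParams,
    PairedCountTable,
    gauss_jacobi_rule,
    log_conditional_pmf,
    log_likelihood,
    log_marginal,
    score,
    success_prob,
)

from conftest import random_pair_set


def beta_binomial_logpmf(a, s, alpha, beta):
    """Independent closed-form reference for the equal-totals marginal."""
    b = s - a
    return (
        special.gammaln(s + 1)
        - special.gammaln(a + 1)
        - special.gammaln(b + 1)
        + special.betaln(a + alpha, b + beta)
        - special.betaln(alpha, beta)
    )


class TestSuccessProb:
    def test_no_effect_equal_totals(self):
        assert success_prob(1.0, 500, 500) == pytest.approx(0.5)

    def test_fold_change_cancels_total_imbalance(self):
        assert success_prob(2.0, 100, 200) == pytest.approx(0.5)

    def test_monotone_in_phi_with_unit_limit(self):
        phis = np.logspace(-3, 6, 40)
        ps = [success_prob(p, 120, 80) for p in phis]
        assert np.all(np.diff(ps) > 0)
        assert ps[-1] > 0.999999 and ps[0] < 1e-2

    def test_rejects_nonpositive_phi(self):
        with pytest.raises(ValueError):
            success_prob(0.0, 10, 10)


class TestConditionalPmf:
    def test_standard_binomial(self):
        assert log_conditional_pmf(2, 5, 0.5, v=1.0) == pytest.approx(np.log(0.3125))

    def test_small_v_approaches_uniform(self):
        val = log_conditional_pmf(2, 5, 0.3, v=1e-9)
        assert val == pytest.approx(np.log(1.0 / 6.0), abs=1e-6)

    @pytest.mark.parametrize("a,s,p,v", [(2, 5, 0.5, 3.0), (0, 7, 0.2, 0.4), (6, 9, 0.8, 2.5)])
    def test_matches_direct_power_normalization(self, a, s, p, v):
        k = np.arange(s + 1)
        pmf = special.comb(s, k) * p**k * (1 - p) ** (s - k)
        expected = np.log(pmf[a] ** v / np.sum(pmf**v))
        assert log_conditional_pmf(a, s, p, v) == pytest.approx(expected, abs=1e-10)

    def test_sums_to_one(self):
        for v in (0.2, 1.0, 5.0):
            total = sum(np.exp(log_conditional_pmf(a, 12, 0.37, v)) for a in range(13))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError):
            log_conditional_pmf(6, 5, 0.5)


class TestGaussJacobiRule:
    def test_legendre_special_case(self):
        rule = gauss_jacobi_rule(1.0, 1.0, 16)
        assert rule.weights.sum() == pytest.approx(2.0, abs=1e-12)
        # integrates x^4 exactly
        assert rule.weights @ rule.nodes**4 == pytest.approx(2.0 / 5.0, abs=1e-12)

    def test_chebyshev_like_moment(self):
        # against weight (1-z^2)^(1/2): integral of z^2 is pi/8
        rule = gauss_jacobi_rule(1.5, 1.5, 8)
        assert rule.weights @ rule.nodes**2 == pytest.approx(np.pi / 8.0, abs=1e-12)

    def test_symmetric_shapes_give_symmetric_nodes(self):
        rule = gauss_jacobi_rule(2.5, 2.5, 11)
        assert rule.nodes == pytest.approx(-rule.nodes[::-1], abs=1e-12)

    @pytest.mark.parametrize("a0,b0", [(0.7, 1.3), (1.5, 1.5), (3.0, 0.5), (10.0, 2.0)])
    def test_total_mass_identity(self, a0, b0):
        rule = gauss_jacobi_rule(a0, b0, 24)
        expected = 2.0 ** (a0 + b0 - 1.0) * special.beta(a0, b0)
        assert rule.weights.sum() == pytest.approx(expected, rel=1e-10)

    def test_polynomial_exactness(self):
        a0, b0, m = 1.8, 0.9, 6
        rule = gauss_jacobi_rule(a0, b0, m)
        rng = np.random.default_rng(5)
        coef = rng.normal(size=2 * m)  # degree 2m-1
        poly = np.polynomial.Polynomial(coef)
        exact, _ = integrate.quad(
            lambda z: poly(z) * (1 - z) ** (a0 - 1) * (1 + z) ** (b0 - 1), -1, 1
        )
        assert rule.weights @ poly(rule.nodes) == pytest.approx(exact, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gauss_jacobi_rule(-1.0, 1.0, 8)
        with pytest.raises(ValueError):
            gauss_jacobi_rule(1.0, 1.0, 1)


def table(a, b, ta, tb):
    return PairedCountTable(a, b, ta, tb, "s")


class TestLogMarginal:
    def test_uniform_prior_equal_totals_is_discrete_uniform(self):
        lm = log_marginal(table(2, 3, 900, 900), IbbParams(1.0, 1.0))
        assert lm == pytest.approx(np.log(1.0 / 6.0), abs=1e-12)

    def test_zero_pair_total_is_point_mass(self):
        assert log_marginal(table(0, 0, 10, 10), IbbParams(2.0, 3.0)) == 0.0

    def test_quadrature_matches_beta_binomial_closed_form(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            s = int(rng.integers(1, 41))
            a = int(rng.integers(0, s + 1))
            alpha = float(np.exp(rng.uniform(np.log(0.2), np.log(50.0))))
            beta = float(np.exp(rng.uniform(np.log(0.2), np.log(50.0))))
            t = table(a, s - a, 700, 700)
            lm = log_marginal(t, IbbParams(alpha, beta), method="jacobi")
            assert lm == pytest.approx(
                beta_binomial_logpmf(a, s, alpha, beta), abs=1e-8
            )

    def test_tanh_sinh_agrees_with_jacobi_at_v_one(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            s = int(rng.integers(1, 41))
            a = int(rng.integers(0, s + 1))
            t = table(a, s - a, 500, 2000)
            params = IbbParams(
                float(rng.uniform(0.3, 20.0)), float(rng.uniform(0.3, 20.0))
            )
            gj = log_marginal(t, params, method="jacobi")
            ts = log_marginal(t, params, method="tanh_sinh")
            assert ts == pytest.approx(gj, abs=1e-9)

    def test_normalization_over_support(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            s = int(rng.integers(1, 41))
            alpha = float(np.exp(rng.uniform(np.log(0.2), np.log(50.0))))
            beta = float(np.exp(rng.uniform(np.log(0.2), np.log(50.0))))
            v = float(rng.choice([0.2, 1.0, 5.0]))
            params = IbbParams(alpha, beta, v)
            lse = special.logsumexp(
                [log_marginal(table(a, s - a, 500, 2000), params) for a in range(s + 1)]
            )
            assert abs(np.expm1(lse)) < 1e-8

    def test_adaptive_integration_oracle(self):
        # the same integrand handed to an independent adaptive integrator
        rng = np.random.default_rng(19)
        for _ in range(20):
            s = int(rng.integers(1, 31))
            a = int(rng.integers(0, s + 1))
            ta, tb = float(rng.integers(200, 2000)), float(rng.integers(200, 2000))
            alpha = float(rng.uniform(0.5, 10.0))
            beta = float(rng.uniform(0.5, 10.0))
            v = float(rng.choice([0.5, 1.0, 2.0]))

            def integrand(u):
                p = u * ta / (u * ta + (1 - u) * tb)
                return np.exp(
                    log_conditional_pmf(a, s, p, v)
                    + (alpha - 1) * np.log(u)
                    + (beta - 1) * np.log1p(-u)
                    - special.betaln(alpha, beta)
                )

            expected, err = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-12, limit=200)
            lm = log_marginal(table(a, s - a, int(ta), int(tb)), IbbParams(alpha, beta, v))
            assert np.exp(lm) == pytest.approx(expected, abs=max(1e-6, 10 * err))

    def test_general_v_path_matches_v_one_path(self):
        t = table(7, 12, 300, 900)
        params = IbbParams(2.5, 4.0, 1.0)
        direct = log_marginal(t, params, method="jacobi")
        forced = log_marginal(t, params, method="tanh_sinh")
        assert forced == pytest.approx(direct, abs=1e-9)


class TestLogLikelihood:
    def test_single_pair_reduces_to_marginal(self):
        t = table(4, 9, 100, 150)
        ps = FeaturePairSet("f", (t,))
        params = IbbParams(2.0, 3.0)
        assert log_likelihood(ps, params) == pytest.approx(
            log_marginal(t, params), abs=1e-12
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(31)
        ps = random_pair_set(rng, n_pairs=5)
        params = IbbParams(1.7, 3.3)
        base = log_likelihood(ps, params)
        perm = FeaturePairSet("f", tuple(reversed(ps.pairs)))
        assert log_likelihood(perm, params) == pytest.approx(base, abs=1e-12)

    def test_label_swap_symmetry(self):
        # swapping before/after everywhere and exchanging alpha and beta
        # leaves the likelihood unchanged
        rng = np.random.default_rng(37)
        for _ in range(10):
            ps = random_pair_set(rng, n_pairs=4)
            alpha, beta = float(rng.uniform(0.5, 10)), float(rng.uniform(0.5, 10))
            v = float(rng.choice([0.5, 1.0, 2.0]))
            direct = log_likelihood(ps, IbbParams(alpha, beta, v))
            swapped = log_likelihood(ps.swapped(), IbbParams(beta, alpha, v))
            assert swapped == pytest.approx(direct, abs=1e-7)

    def test_score_matches_finite_differences(self):
        rng = np.random.default_rng(41)
        h = 1e-6
        for _ in range(10):
            ps = random_pair_set(rng, n_pairs=4)
            alpha = float(rng.uniform(0.5, 15.0))
            beta = float(rng.uniform(0.5, 15.0))
            v = float(rng.choice([0.5, 1.0, 2.0]))
            grad = score(ps, IbbParams(alpha, beta, v))
            fd = np.array(
                [
                    (
                        log_likelihood(ps, IbbParams(alpha + h, beta, v))
                        - log_likelihood(ps, IbbParams(alpha - h, beta, v))
                    )
                    / (2 * h),
                    (
                        log_likelihood(ps, IbbParams(alpha, beta + h, v))
                        - log_likelihood(ps, IbbParams(alpha, beta - h, v))
                    )
                    / (2 * h),
                ]
            )
            assert grad == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            IbbParams(0.0, 1.0)
        with pytest.raises(ValueError):
            IbbParams(1.0, 1.0, v=-2.0)
        assert IbbParams(6.0, 2.0).fold_change == pytest.approx(3.0)
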