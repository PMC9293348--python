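"""Tests of the one-sided noninferiority/superiority tests.

The constrained MLE is checked against an independent numerical
maximization of the conditional binomial log-likelihood, and the exact
Fisher tail against direct hypergeometric enumeration.
"""

import numpy as np
import pytest
from scipy import optimize, special, stats

from pairscreen import (
    EstimationError,
    TwoBinomialData,
    ak_test,
    constrained_mle,
    from_trial,
    lr_test,
    score_test,
    superiority_test,
    wald_test,
)
from conftest import make_trial, random_tables


def loglik(x_a, n_a, x_b, n_b, p_a, p_b):
    return (
        special.xlogy(x_a, p_a)
        + special.xlogy(n_a - x_a, 1 - p_a)
        + special.xlogy(x_b, p_b)
        + special.xlogy(n_b - x_b, 1 - p_b)
    )


def constrained_mle_oracle(d, delta0):
    """Numerical maximization of the constrained log-likelihood over pi_B."""
    upper = min(1.0, 1.0 / delta0)

    def neg(pb):
        return -loglik(d.x_a, d.n_a, d.x_b, d.n_b, delta0 * pb, pb)

    res = optimize.minimize_scalar(neg, bounds=(1e-12, upper - 1e-12), method="bounded",
                                   options={"xatol": 1e-12})
    return float(res.x)


class TestFromTrial:
    def test_improve_sensitivity_layout(self, improve_sens):
        assert (improve_sens.x_a, improve_sens.n_a) == (39, 41)
        assert (improve_sens.x_b, improve_sens.n_b) == (69, 72)

    def test_improve_fpf_layout(self, improve):
        d = from_trial(improve, "fpf")
        assert (d.x_a, d.n_a, d.x_b, d.n_b) == (278, 375, 327, 476)

    def test_empty_diseased_cells_raise(self, improve):
        import dataclasses

        from pairscreen import ArmFirstA

        broken = dataclasses.replace(
            improve, arm_a=ArmFirstA(0, 0, 327, 149, 7146, 7622)
        )
        with pytest.raises(EstimationError):
            from_trial(broken, "sensitivity")


class TestWald:
    def test_improve_noninferiority(self, improve_sens):
        result = wald_test(improve_sens, 0.9)
        assert round(result.p_one_sided, 3) == 0.013
        assert result.statistic == pytest.approx(2.2313, abs=1e-4)

    def test_null_boundary_gives_half(self):
        d = TwoBinomialData(x_a=45, n_a=100, x_b=50, n_b=100)
        result = wald_test(d, 0.9)
        assert result.statistic == pytest.approx(0.0)
        assert result.p_one_sided == pytest.approx(0.5)

    def test_improve_superiority_margin(self, improve_sens):
        # direct plug-in: pi_hat_A - pi_hat_B over the unrestricted SE
        p_a, p_b = 39 / 41, 69 / 72
        se = np.sqrt(p_a * (1 - p_a) / 41 + p_b * (1 - p_b) / 72)
        result = wald_test(improve_sens, 1.0)
        assert result.statistic == pytest.approx((p_a - p_b) / se)
        assert result.p_one_sided == pytest.approx(stats.norm.sf((p_a - p_b) / se))

    def test_degenerate_variance_raises(self):
        with pytest.raises(EstimationError, match="0.25"):
            wald_test(TwoBinomialData(x_a=10, n_a=10, x_b=5, n_b=5), 0.9)


class TestConstrainedMle:
    def test_improve_closed_form(self, improve_sens):
        pt_a, pt_b = constrained_mle(improve_sens, 0.9)
        assert round(pt_b, 4) == 0.9692
        assert round(pt_a, 4) == 0.8723
        assert pt_a == pytest.approx(0.9 * pt_b)

    def test_margin_one_pools(self):
        d = TwoBinomialData(x_a=5, n_a=10, x_b=5, n_b=10)
        pt_a, pt_b = constrained_mle(d, 1.0)
        assert pt_a == pytest.approx(0.5)
        assert pt_b == pytest.approx(0.5)

    def test_zero_successes_give_zero(self):
        d = TwoBinomialData(x_a=0, n_a=10, x_b=0, n_b=12)
        assert constrained_mle(d, 0.8) == (0.0, 0.0)

    def test_matches_numerical_oracle_on_random_tables(self):
        rng = np.random.default_rng(20240917)
        for d, delta0 in random_tables(rng, 200):
            pt_a, pt_b = constrained_mle(d, delta0)
            assert pt_b == pytest.approx(constrained_mle_oracle(d, delta0), abs=1e-6)
            assert 0.0 <= pt_b <= 1.0
            assert pt_a == pytest.approx(delta0 * pt_b)


class TestScore:
    def test_improve_value_from_printed_formulas(self, improve_sens):
        result = score_test(improve_sens, 0.9)
        assert result.statistic == pytest.approx(1.598, abs=1e-3)
        assert round(result.p_one_sided, 3) == 0.055

    def test_null_boundary_gives_half(self):
        d = TwoBinomialData(x_a=45, n_a=100, x_b=50, n_b=100)
        assert score_test(d, 0.9).p_one_sided == pytest.approx(0.5)

    def test_symmetric_samples_margin_one(self):
        d = TwoBinomialData(x_a=30, n_a=40, x_b=30, n_b=40)
        assert score_test(d, 1.0).statistic == pytest.approx(0.0)

    def test_finite_sample_factor_present(self, improve_sens):
        pt_a, pt_b = constrained_mle(improve_sens, 0.9)
        var = (pt_a * (1 - pt_a) / 41 + 0.81 * pt_b * (1 - pt_b) / 72) * 113 / 112
        expected = (39 / 41 - 0.9 * 69 / 72) / np.sqrt(var)
        assert score_test(improve_sens, 0.9).statistic == pytest.approx(expected)


class TestLikelihoodRatio:
    def test_improve_value(self, improve_sens):
        result = lr_test(improve_sens, 0.9)
        assert result.statistic == pytest.approx(3.165, abs=1e-3)
        assert round(result.p_one_sided, 3) == 0.038

    def test_clamped_branch(self):
        # pi_hat_A < delta0 * pi_hat_B
        d = TwoBinomialData(x_a=30, n_a=100, x_b=80, n_b=100)
        result = lr_test(d, 0.9)
        assert result.statistic == 0.0
        assert result.p_one_sided == 1.0

    def test_identical_samples_margin_one(self):
        d = TwoBinomialData(x_a=30, n_a=40, x_b=30, n_b=40)
        result = lr_test(d, 1.0)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_statistic_nonnegative_and_zero_only_when_clamped(self):
        rng = np.random.default_rng(7)
        for d, delta0 in random_tables(rng, 200):
            result = lr_test(d, delta0)
            assert result.statistic >= 0.0
            p_a, p_b = d.pi_hat
            if p_a - delta0 * p_b < 0:
                assert result.statistic == 0.0

    def test_agrees_with_squared_score_for_large_balanced_samples(self):
        d = TwoBinomialData(x_a=8150, n_a=10000, x_b=8000, n_b=10000)
        t_lr = lr_test(d, 1.0).statistic
        t_s = score_test(d, 1.0).statistic
        assert t_lr == pytest.approx(t_s**2, rel=0.02)


class TestMonotonicity:
    @pytest.mark.parametrize("func", [wald_test, score_test, lr_test])
    def test_p_value_nonincreasing_in_x_a(self, func):
        n_a, x_b, n_b, delta0 = 50, 40, 50, 0.9
        pvals = [
            func(TwoBinomialData(x_a=x, n_a=n_a, x_b=x_b, n_b=n_b), delta0).p_one_sided
            for x in range(1, n_a)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(pvals, pvals[1:]))


class TestSuperiority:
    def test_fisher_exact_tail_matches_enumeration(self):
        d = TwoBinomialData(x_a=9, n_a=10, x_b=1, n_b=10)
        # P(X >= 9), X ~ Hypergeom(N=20, successes=10, draws=10)
        expected = stats.hypergeom.sf(8, 20, 10, 10)
        assert expected == pytest.approx(101 / 184756)
        assert superiority_test(d, "fisher").p_one_sided == pytest.approx(expected)

    def test_identical_samples_not_significant(self):
        d = TwoBinomialData(x_a=5, n_a=10, x_b=5, n_b=10)
        assert superiority_test(d, "fisher").p_one_sided >= 0.5
        assert superiority_test(d, "chi2").p_one_sided >= 0.5

    def test_improve_sensitivity_direction(self, improve_sens):
        # pi_hat_A < pi_hat_B, so the one-sided p must exceed one half
        assert superiority_test(improve_sens, "fisher").p_one_sided > 0.5

    def test_chi2_is_signed_root_of_pearson(self):
        d = TwoBinomialData(x_a=30, n_a=40, x_b=20, n_b=40)
        chi2_stat = stats.chi2_contingency(
            [[30, 10], [20, 20]], correction=False
        ).statistic
        assert superiority_test(d, "chi2").statistic ** 2 == pytest.approx(chi2_stat)

    def test_degenerate_margins_warn(self):
        d = TwoBinomialData(x_a=10, n_a=10, x_b=10, n_b=10)
        with pytest.warns(UserWarning):
            assert superiority_test(d, "chi2").p_one_sided == 1.0


class TestAkBootstrapTest:
    def test_improve_rejects_at_margin(self, improve):
        result = ak_test(improve, 0.9, b_boot=2000, seed=11)
        assert result.p_one_sided < 0.05

    def test_mirror_arms_near_half(self):
        counts = make_trial([40, 10, 25, 25, 400], [40, 10, 25, 25, 400])
        result = ak_test(counts, 1.0, b_boot=2000, seed=3)
        assert 0.3 < result.p_one_sided < 0.7

    def test_reproducible_under_seed(self, improve):
        p1 = ak_test(improve, 0.9, b_boot=500, seed=5).p_one_sided
        p2 = ak_test(improve, 0.9, b_boot=500, seed=5).p_one_sided
        assert p1 == p2

    def test_zero_bootstrap_raises(self, improve):
        with pytest.raises(EstimationError):
            ak_test(improve, 0.9, b_boot=0, seed=1)
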