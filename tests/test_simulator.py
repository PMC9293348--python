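"""Tests of the trial data-generating mechanism: the Plackett joint, cell
probabilities, and the multinomial trial draws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pairscreen import (
    ScenarioConfig,
    arm_cell_probs,
    joint_from_margins_or,
    simulate_trial,
    simulate_trial_cells,
)


class TestPlackettJoint:
    def test_known_symmetric_case(self):
        p11 = joint_from_margins_or(0.5, 0.5, 4.0)
        assert p11 == pytest.approx(1 / 3)
        # back-substitute the odds ratio
        p10 = 0.5 - p11
        assert (p11 * p11) / (p10 * p10) == pytest.approx(4.0)

    def test_independence(self):
        assert joint_from_margins_or(0.3, 0.7, 1.0) == pytest.approx(0.21)

    def test_degenerate_margin(self):
        assert joint_from_margins_or(0.0, 0.5, 3.0) == 0.0
        assert joint_from_margins_or(1.0, 0.5, 3.0) == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        p1=st.floats(0.01, 0.99),
        p2=st.floats(0.01, 0.99),
        psi=st.floats(0.05, 20.0),
    )
    def test_reproduces_odds_ratio_within_frechet_bounds(self, p1, p2, psi):
        p11 = joint_from_margins_or(p1, p2, psi)
        assert max(0.0, p1 + p2 - 1.0) - 1e-12 <= p11 <= min(p1, p2) + 1e-12
        p10, p01 = p1 - p11, p2 - p11
        p00 = 1 - p1 - p2 + p11
        if min(p10, p01, p00, p11) > 1e-9:
            assert (p11 * p00) / (p10 * p01) == pytest.approx(psi, rel=1e-6)


class TestArmCellProbs:
    def test_mirror_symmetry_for_identical_tests(self):
        config = ScenarioConfig(prev_a=0.05, rel_sens=1.0, or_d=1.0, or_nd=1.0)
        pa = arm_cell_probs(config, "A").as_array()
        pb = arm_cell_probs(config, "B").as_array()
        assert pa == pytest.approx(pb)

    def test_zero_prevalence_leaves_only_nondiseased(self):
        config = ScenarioConfig(prev_a=0.0)
        p = arm_cell_probs(config, "A")
        assert p.p_d_pos_pos == 0.0
        assert p.p_d_pos_neg == 0.0
        assert p.p_nd_pos_pos > 0.0

    def test_first_cell_under_independence(self):
        config = ScenarioConfig(prev_a=0.01, sens_b=0.95, rel_sens=1.0,
                                spec_a=0.95, spec_b=0.95)
        p = arm_cell_probs(config, "A")
        assert p.p_d_pos_pos == pytest.approx(0.01 * 0.95 * 0.95)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        prev=st.floats(0.0, 0.3),
        ratio=st.floats(0.25, 1.5),
        sens_b=st.floats(0.5, 1.0),
        rel=st.floats(0.5, 1.0),
        spec=st.floats(0.7, 1.0),
        or_d=st.floats(0.2, 10.0),
        first=st.sampled_from(["A", "B"]),
    )
    def test_probabilities_nonnegative_and_sum_to_one(
        self, prev, ratio, sens_b, rel, spec, or_d, first
    ):
        config = ScenarioConfig(
            prev_a=prev, prev_ratio=ratio, sens_b=sens_b, rel_sens=rel,
            spec_a=spec, spec_b=spec, or_d=or_d, or_nd=or_d,
        )
        p = arm_cell_probs(config, first).as_array()
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_order_invariance_of_double_positive_given_disease(self):
        """P(A+,B+|D+) is the same whichever test is administered first."""
        config = ScenarioConfig(prev_a=0.05, prev_ratio=0.5, sens_b=0.9,
                                rel_sens=0.95, or_d=3.0)
        pa = arm_cell_probs(config, "A")
        pb = arm_cell_probs(config, "B")
        assert pa.p_d_pos_pos / config.prev_a == pytest.approx(
            pb.p_d_pos_pos / config.prev_b
        )


class TestSimulateTrial:
    def test_withdrawal_reduces_screened(self):
        config = ScenarioConfig(m_per_arm=5000, uptake_b=0.8, seed=1)
        counts = simulate_trial(config)
        assert counts.arm_a.n_screened == 5000
        assert counts.arm_b.n_screened == 4000

    def test_deterministic_under_seed(self):
        config = ScenarioConfig(seed=123)
        assert simulate_trial(config) == simulate_trial(config)

    def test_cell_totals_close_under_multinomial(self):
        rng = np.random.default_rng(5)
        config = ScenarioConfig(m_per_arm=777, uptake_a=0.9, uptake_b=0.6)
        cells_a, cells_b = simulate_trial_cells(config, 200, rng)
        assert np.all(cells_a.sum(axis=1) == round(777 * 0.9))
        assert np.all(cells_b.sum(axis=1) == round(777 * 0.6))

    def test_empirical_frequencies_match_probabilities(self):
        """Goodness of fit of one large multinomial draw to the cell model."""
        config = ScenarioConfig(m_per_arm=10**6, prev_a=0.05, or_d=2.0, or_nd=2.0)
        counts = simulate_trial(config, rng=np.random.default_rng(99))
        observed = np.array([
            counts.arm_a.n_dab, counts.arm_a.n_dab_not, counts.arm_a.n_ndab,
            counts.arm_a.n_ndab_not, counts.arm_a.n_aneg,
        ])
        expected = arm_cell_probs(config, "A").as_array() * 10**6
        stat = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(stat, df=4) > 0.001

    def test_first_test_positivity_rate(self):
        config = ScenarioConfig(m_per_arm=10**6, prev_a=0.10, sens_b=0.85,
                                spec_a=0.90, spec_b=0.90)
        counts = simulate_trial(config, rng=np.random.default_rng(17))
        pos = counts.arm_a.n_screened - counts.arm_a.n_aneg
        expected = 0.10 * config.sens_a + 0.90 * 0.10
        assert pos / counts.arm_a.n_screened == pytest.approx(expected, rel=0.02)
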