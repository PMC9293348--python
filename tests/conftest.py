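import pytest

from pairscreen import ArmFirstA, ArmFirstB, TrialCounts, TwoBinomialData, from_trial, improve_fixture


def make_trial(a_cells, b_cells, m_a=None, m_b=None):
    """Trial counts from two five-cell lists (screened totals derived)."""
    arm_a = ArmFirstA(*a_cells, sum(a_cells))
    arm_b = ArmFirstB(*b_cells, sum(b_cells))
    return TrialCounts(
        arm_a=arm_a,
        arm_b=arm_b,
        m_a=arm_a.n_screened if m_a is None else m_a,
        m_b=arm_b.n_screened if m_b is None else m_b,
    )


def random_tables(rng, count):
    """Random small two-binomial tables with margins, for oracle checks."""
    for _ in range(count):
        n_a = int(rng.integers(1, 60))
        n_b = int(rng.integers(1, 60))
        x_a = int(rng.integers(0, n_a + 1))
        x_b = int(rng.integers(0, n_b + 1))
        delta0 = float(rng.uniform(0.5, 1.0))
        yield TwoBinomialData(x_a=x_a, n_a=n_a, x_b=x_b, n_b=n_b), delta0


@pytest.fixture(scope="session")
def improve():
    """Counts of the IMPROVE worked example."""
    return improve_fixture()


@pytest.fixture(scope="session")
def improve_sens(improve):
    """IMPROVE reduced to the diseased two-binomial layout (39/41 vs 69/72)."""
    return from_trial(improve, "sensitivity")
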