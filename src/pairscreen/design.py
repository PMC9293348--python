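"""Sample-size planning for the conditional Wald noninferiority test.

The planning pipeline has three steps:

1. translate the anticipated test characteristics (standard-test
   sensitivity, relative sensitivity under the alternative, within-subject
   odds ratio in diseased subjects) into the two conditional proportions
   ``pi_A``, ``pi_B`` compared by the tests;
2. compute the required numbers of diseased first-test-positive subjects
   per arm with the Farrington-Manning sample-size formula for a
   noninferiority comparison of two proportions at ratio margin
   ``delta0`` (null variance evaluated at the margin-constrained MLE
   limits);
3. inflate those event counts to numbers randomized per arm using the
   anticipated screening uptake, screened-population prevalence, and
   first-test sensitivity of each arm.

With 1:1 randomization the event-allocation ratio is not free: it is
fixed by the uptake/prevalence/sensitivity products of the two arms, and
the inflation step sizes on whichever arm binds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .nitests import TwoBinomialData, constrained_mle
from .simulator import joint_from_margins_or

__all__ = [
    "DesignSpec",
    "DesignResult",
    "DesignError",
    "design_proportions",
    "fm_sample_size",
    "randomized_per_arm",
]


class DesignError(ValueError):
    """The design specification admits no finite sample size."""


@dataclass(frozen=True)
class DesignSpec:
    """Anticipated trial characteristics for sample-size planning.

    ``delta0`` is the noninferiority margin, ``delta1`` the relative
    sensitivity under the alternative, ``sens_b`` the standard-test
    sensitivity, ``or_diseased`` the odds ratio linking the two test
    outcomes in diseased subjects, ``prev_a``/``prev_b`` the anticipated
    screened-population prevalences and ``uptake_a``/``uptake_b`` the
    anticipated uptake proportions.  ``alpha`` is the one-sided level.
    """

    delta0: float
    delta1: float
    sens_b: float
    or_diseased: float = 1.0
    prev_a: float = 0.01
    prev_b: float = 0.01
    uptake_a: float = 1.0
    uptake_b: float = 1.0
    alpha: float = 0.05
    power: float = 0.80
    target_test: str = "wald"

    def __post_init__(self) -> None:
        if self.target_test not in ("wald", "score"):
            raise ValueError(f"target_test must be 'wald' or 'score', got {self.target_test!r}")
        for name in ("delta0", "sens_b", "uptake_a", "uptake_b", "prev_a", "prev_b", "power"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.delta1 * self.sens_b > 1.0 + 1e-12:
            raise ValueError("delta1 * sens_b must not exceed 1")
        if self.delta0 > self.delta1:
            raise ValueError("margin delta0 must not exceed the alternative delta1")
        if self.or_diseased <= 0:
            raise ValueError("or_diseased must be > 0")

    @property
    def sens_a(self) -> float:
        return min(self.delta1 * self.sens_b, 1.0)


@dataclass(frozen=True)
class DesignResult:
    """Required events and randomized numbers per arm.

    ``n_events_a`` is the required number of diseased A-positives in the
    A-first arm (the ``pi_B`` sample), ``n_events_b`` the required number
    of diseased B-positives in the B-first arm (the ``pi_A`` sample).
    """

    n_events_a: int
    n_events_b: int
    m_per_arm: int
    pi_a_alt: float
    pi_b_alt: float

    def to_record(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def design_proportions(spec: DesignSpec) -> tuple[float, float]:
    """Conditional proportions ``(pi_A, pi_B)`` under the alternative.

    With ``p11`` the diseased double-positive probability implied by the
    margins and odds ratio, ``pi_A = p11 / sens_b`` and
    ``pi_B = p11 / sens_a``, so that ``pi_A / pi_B = delta1`` exactly.
    """
    p11 = joint_from_margins_or(spec.sens_a, spec.sens_b, spec.or_diseased)
    return p11 / spec.sens_b, p11 / spec.sens_a


def fm_sample_size(
    pi_a: float,
    pi_b: float,
    delta0: float,
    alpha: float = 0.05,
    power: float = 0.80,
    kappa: float = 1.0,
    null_variance: str = "constrained",
) -> tuple[int, int]:
    """Farrington-Manning-style event counts for the one-sided ratio comparison.

    Returns ``(n_a_events, n_b_events)`` with ``n_b_events =
    ceil(kappa * n_a_events)``, where ``n_a_events`` is the smallest
    integer such that the normal-approximation power of the level-``alpha``
    test of ``H0: pi_A <= delta0 * pi_B`` reaches ``power``:

    ``n_a = (z_{1-alpha}*sigma0 + z_{power}*sigma1)^2 / (pi_A - delta0*pi_B)^2``

    with ``sigma1^2 = pi_A(1-pi_A) + delta0^2 pi_B(1-pi_B)/kappa`` evaluated
    at the alternative, and ``sigma0^2`` the same form at either the
    large-sample limits of the ``delta0``-constrained MLE
    (``null_variance="constrained"``, the classical Farrington-Manning form,
    which is the null variance of the score statistic) or at the alternative
    itself (``null_variance="unconstrained"``, which is the large-sample
    limit of the Wald statistic's variance estimate and therefore sizes the
    Wald test).  The two variants differ materially when the proportions
    are near 1: the constrained form requires more events and overpowers
    the Wald test.
    """
    effect = pi_a - delta0 * pi_b
    if effect <= 0:
        raise DesignError(
            f"alternative pi_A ({pi_a:.4f}) must exceed delta0*pi_B "
            f"({delta0 * pi_b:.4f}); no finite sample size exists"
        )
    if kappa <= 0:
        raise DesignError("allocation ratio kappa must be > 0")
    sigma1_sq = pi_a * (1 - pi_a) + delta0**2 * pi_b * (1 - pi_b) / kappa
    if null_variance == "constrained":
        # constrained-MLE limits: counts replaced by their per-n_a expectations
        pt_a, pt_b = constrained_mle(
            TwoBinomialData(x_a=pi_a, n_a=1.0, x_b=kappa * pi_b, n_b=kappa), delta0
        )
        sigma0_sq = pt_a * (1 - pt_a) + delta0**2 * pt_b * (1 - pt_b) / kappa
    elif null_variance == "unconstrained":
        sigma0_sq = sigma1_sq
    else:
        raise ValueError(
            f"null_variance must be 'constrained' or 'unconstrained', got {null_variance!r}"
        )
    z_a = stats.norm.ppf(1 - alpha)
    z_p = stats.norm.ppf(power)
    n_a = (z_a * math.sqrt(sigma0_sq) + z_p * math.sqrt(sigma1_sq)) ** 2 / effect**2
    n_a_events = math.ceil(n_a - 1e-9)
    return n_a_events, math.ceil(kappa * n_a_events - 1e-9)


def randomized_per_arm(spec: DesignSpec) -> DesignResult:
    """Numbers to randomize per arm for the target power.

    The event-allocation ratio ``kappa = E[N_DA^A] / E[N_DB^B]`` implied by
    1:1 randomization is
    ``(uptake_a * prev_a * sens_a) / (uptake_b * prev_b * sens_b)``; the
    required events are inflated by each arm's expected event rate per
    randomized subject and the larger randomized number is used for both
    arms.
    """
    pi_a, pi_b = design_proportions(spec)
    rate_a = spec.uptake_a * spec.prev_a * spec.sens_a  # diseased A+ per randomized, arm A
    rate_b = spec.uptake_b * spec.prev_b * spec.sens_b  # diseased B+ per randomized, arm B
    if rate_a <= 0 or rate_b <= 0:
        raise DesignError("event rates must be positive in both arms")
    kappa = rate_a / rate_b
    null_variance = "unconstrained" if spec.target_test == "wald" else "constrained"
    ev_pi_a, ev_pi_b = fm_sample_size(
        pi_a, pi_b, spec.delta0, spec.alpha, spec.power, kappa, null_variance
    )
    # ev_pi_a counts the pi_A sample (N_DB^B, arm B); ev_pi_b the pi_B sample (N_DA^A, arm A)
    m = math.ceil(max(ev_pi_a / rate_b, ev_pi_b / rate_a))
    return DesignResult(
        n_events_a=ev_pi_b,
        n_events_b=ev_pi_a,
        m_per_arm=m,
        pi_a_alt=pi_a,
        pi_b_alt=pi_b,
    )
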