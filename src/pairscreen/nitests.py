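"""Noninferiority and superiority tests for the relative sensitivity.

After conditioning on disease status and on the numbers positive on the
first test, the trial reduces to two independent binomial samples:

* ``x_a`` successes out of ``n_a = N_DB^B`` for ``pi_A = P(A+ | B+, D+)``
  (arm screened with the standard test B first), and
* ``x_b`` successes out of ``n_b = N_DA^A`` for ``pi_B = P(B+ | A+, D+)``
  (arm screened with the new test A first),

and the relative sensitivity equals the risk ratio ``pi_A / pi_B``.  The
one-sided hypothesis ``H0: pi_A / pi_B <= delta0`` versus
``H1: pi_A / pi_B > delta0`` is tested with the Wald statistic, the
Miettinen-Nurminen score statistic built on the constrained MLE under
``pi_A = delta0 * pi_B``, or the likelihood-ratio statistic whose null
distribution is the chi-bar-square mixture ``0.5*chi2_0 + 0.5*chi2_1``.
For superiority (``delta0 = 1``) the one-sided chi-square and Fisher exact
tests are also provided, as is a bootstrap test built on the
Alonzo-Kittelson estimator.

The ``_*_core`` helpers operate on numpy arrays so that simulation studies
can evaluate thousands of replicates at once; the public functions wrap
them for scalar data with full validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .counts_model import TrialCounts
from .estimators import EstimationError, _ak_estimate_from_cells, ak_relative_sensitivity

__all__ = [
    "TwoBinomialData",
    "TestResult",
    "from_trial",
    "wald_test",
    "constrained_mle",
    "score_test",
    "lr_test",
    "superiority_test",
    "ak_test",
]


@dataclass(frozen=True)
class TwoBinomialData:
    """Two independent binomial samples for the conditional comparison.

    Counts may be fractional: the simulation-protocol zero-cell correction
    adds 0.25 to each of the four cells when any is zero.
    """

    x_a: float
    n_a: float
    x_b: float
    n_b: float

    def __post_init__(self) -> None:
        if self.n_a <= 0 or self.n_b <= 0:
            raise ValueError("both sample sizes must be positive")
        if not (0 <= self.x_a <= self.n_a and 0 <= self.x_b <= self.n_b):
            raise ValueError("successes must satisfy 0 <= x <= n")

    @property
    def pi_hat(self) -> tuple[float, float]:
        """Unrestricted MLEs ``(pi_hat_A, pi_hat_B)``."""
        return self.x_a / self.n_a, self.x_b / self.n_b


@dataclass(frozen=True)
class TestResult:
    """Outcome of a one-sided test of ``H0: pi_A/pi_B <= delta0``."""

    statistic: float
    p_one_sided: float
    margin: float
    method: str
    pi_hat: tuple[float, float]
    pi_tilde: tuple[float, float] | None = None

    def to_record(self) -> dict:
        record = {
            "method": self.method,
            "statistic": self.statistic,
            "p_one_sided": self.p_one_sided,
            "margin": self.margin,
            "pi_hat": list(self.pi_hat),
        }
        if self.pi_tilde is not None:
            record["pi_tilde"] = list(self.pi_tilde)
        return record


def from_trial(counts: TrialCounts, target: str = "sensitivity") -> TwoBinomialData:
    """Reduce trial counts to the two-binomial layout.

    ``target="sensitivity"`` uses the verified diseased cells,
    ``target="fpf"`` the verified nondiseased cells.
    """
    if target == "sensitivity":
        x_a, n_a = counts.arm_b.n_dab, counts.arm_b.n_dbb
        x_b, n_b = counts.arm_a.n_dab, counts.arm_a.n_daa
    elif target == "fpf":
        x_a, n_a = counts.arm_b.n_ndab, counts.arm_b.n_ndbb
        x_b, n_b = counts.arm_a.n_ndab, counts.arm_a.n_ndaa
    else:
        raise ValueError(f"target must be 'sensitivity' or 'fpf', got {target!r}")
    if n_a == 0 or n_b == 0:
        raise EstimationError(f"no verified {target} events in one of the arms")
    return TwoBinomialData(x_a=x_a, n_a=n_a, x_b=x_b, n_b=n_b)


def _check_margin(delta0: float) -> None:
    if not 0.0 < delta0 <= 1.0:
        raise ValueError(f"margin delta0 must be in (0, 1], got {delta0}")


# ---------------------------------------------------------------------------
# array cores

def _wald_core(x_a, n_a, x_b, n_b, delta0):
    """Wald statistic with the unrestricted-MLE variance; NaN if degenerate."""
    p_a = x_a / n_a
    p_b = x_b / n_b
    var = p_a * (1.0 - p_a) / n_a + delta0**2 * p_b * (1.0 - p_b) / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, (p_a - delta0 * p_b) / np.sqrt(var), np.nan)


def _constrained_core(x_a, n_a, x_b, n_b, delta0):
    """Constrained MLE of pi_B under pi_A = delta0 * pi_B (closed form).

    The profile log-likelihood stationarity condition is the quadratic
    ``a*t^2 + b*t + c = 0`` with ``a = delta0*(n_b + n_a)``,
    ``b = -(delta0*n_a + x_a + n_b + delta0*x_b)``, ``c = x_a + x_b``;
    the admissible root is ``(-b - sqrt(b^2 - 4ac)) / (2a)``.
    """
    a = delta0 * (n_b + n_a)
    b = -(delta0 * n_a + x_a + n_b + delta0 * x_b)
    c = x_a + x_b
    disc = b * b - 4.0 * a * c
    # roundoff can push a zero discriminant slightly negative
    disc = np.maximum(disc, 0.0)
    t = (-b - np.sqrt(disc)) / (2.0 * a)
    return np.clip(t, 0.0, 1.0)


def _score_core(x_a, n_a, x_b, n_b, delta0):
    """Miettinen-Nurminen score statistic with the finite-sample factor."""
    pt_b = _constrained_core(x_a, n_a, x_b, n_b, delta0)
    pt_a = delta0 * pt_b
    n = n_a + n_b
    var = (pt_a * (1.0 - pt_a) / n_a + delta0**2 * pt_b * (1.0 - pt_b) / n_b) * n / (n - 1.0)
    p_a = x_a / n_a
    p_b = x_b / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, (p_a - delta0 * p_b) / np.sqrt(var), np.nan)


def _cond_loglik(x_a, n_a, x_b, n_b, p_a, p_b):
    """Conditional binomial log-likelihood; 0*log(0) treated as 0."""
    return (
        special.xlogy(x_a, p_a)
        + special.xlogy(n_a - x_a, 1.0 - p_a)
        + special.xlogy(x_b, p_b)
        + special.xlogy(n_b - x_b, 1.0 - p_b)
    )


def _lr_core(x_a, n_a, x_b, n_b, delta0):
    """Likelihood-ratio statistic, clamped to 0 when pi_hat_A < delta0*pi_hat_B."""
    p_a = x_a / n_a
    p_b = x_b / n_b
    pt_b = _constrained_core(x_a, n_a, x_b, n_b, delta0)
    pt_a = delta0 * pt_b
    t = -2.0 * (
        _cond_loglik(x_a, n_a, x_b, n_b, pt_a, pt_b)
        - _cond_loglik(x_a, n_a, x_b, n_b, p_a, p_b)
    )
    t = np.maximum(t, 0.0)  # the unconstrained optimum can only be higher
    return np.where(p_a - delta0 * p_b >= 0, t, 0.0)


def _lr_pvalue(t):
    """Upper-tail p under the chi-bar-square mixture 0.5*chi2_0 + 0.5*chi2_1.

    At ``t = 0`` the whole point mass of chi2_0 is in the tail, so p = 1;
    the limit from the right is 0.5 (documented discontinuity).
    """
    return np.where(t > 0, 0.5 * stats.chi2.sf(t, df=1), 1.0)


# ---------------------------------------------------------------------------
# public scalar API

def wald_test(d: TwoBinomialData, delta0: float) -> TestResult:
    """One-sided Wald test of ``H0: pi_A/pi_B <= delta0``.

    Uses the unrestricted-MLE variance of ``pi_hat_A - delta0*pi_hat_B``;
    the p-value is the upper standard-normal tail.  Asymptotically valid
    but anti-conservative with few events.
    """
    _check_margin(delta0)
    t = float(_wald_core(d.x_a, d.n_a, d.x_b, d.n_b, delta0))
    if math.isnan(t):
        raise EstimationError(
            "Wald variance is zero (both proportions at 0 or 1); apply the "
            "0.25 zero-cell correction"
        )
    return TestResult(
        statistic=t,
        p_one_sided=float(stats.norm.sf(t)),
        margin=delta0,
        method="wald",
        pi_hat=d.pi_hat,
    )


def constrained_mle(d: TwoBinomialData, delta0: float) -> tuple[float, float]:
    """Maximum-likelihood ``(pi_tilde_A, pi_tilde_B)`` under ``pi_A = delta0*pi_B``."""
    _check_margin(delta0)
    pt_b = float(_constrained_core(d.x_a, d.n_a, d.x_b, d.n_b, delta0))
    return delta0 * pt_b, pt_b


def score_test(d: TwoBinomialData, delta0: float) -> TestResult:
    """Miettinen-Nurminen score test of ``H0: pi_A/pi_B <= delta0``.

    The variance is evaluated at the constrained MLE and multiplied by the
    finite-sample factor ``(n_a + n_b) / (n_a + n_b - 1)``; the p-value is
    the upper standard-normal tail.
    """
    _check_margin(delta0)
    if d.n_a + d.n_b < 2:
        raise ValueError("score test needs n_a + n_b >= 2")
    t = float(_score_core(d.x_a, d.n_a, d.x_b, d.n_b, delta0))
    if math.isnan(t):
        raise EstimationError("score variance is zero at the constrained MLE")
    return TestResult(
        statistic=t,
        p_one_sided=float(stats.norm.sf(t)),
        margin=delta0,
        method="score",
        pi_hat=d.pi_hat,
        pi_tilde=constrained_mle(d, delta0),
    )


def lr_test(d: TwoBinomialData, delta0: float) -> TestResult:
    """Likelihood-ratio test of ``H0: pi_A/pi_B <= delta0``.

    The statistic is ``-2 (l_C(pi_tilde) - l_C(pi_hat))`` when the estimate
    is on the alternative side (``pi_hat_A >= delta0*pi_hat_B``) and 0
    otherwise; p-values come from the chi-bar-square mixture
    ``0.5*chi2_0 + 0.5*chi2_1`` (p = 1 at a clamped statistic).
    """
    _check_margin(delta0)
    t = float(_lr_core(d.x_a, d.n_a, d.x_b, d.n_b, delta0))
    return TestResult(
        statistic=t,
        p_one_sided=float(_lr_pvalue(t)),
        margin=delta0,
        method="lr",
        pi_hat=d.pi_hat,
        pi_tilde=constrained_mle(d, delta0),
    )


def superiority_test(d: TwoBinomialData, method: str = "chi2") -> TestResult:
    """One-sided superiority test (margin 1) in the direction ``pi_A > pi_B``.

    ``method="chi2"`` uses the signed square root of the Pearson statistic
    (no continuity correction) with an upper-normal p-value;
    ``method="fisher"`` the exact conditional hypergeometric tail (no
    mid-p).  Counts must be integers for the Fisher variant.
    """
    p_a, p_b = d.pi_hat
    pooled = (d.x_a + d.x_b) / (d.n_a + d.n_b)
    if method == "chi2":
        var = pooled * (1.0 - pooled) * (1.0 / d.n_a + 1.0 / d.n_b)
        if var == 0:
            warnings.warn("degenerate margins: all successes or all failures", stacklevel=2)
            return TestResult(0.0, 1.0, 1.0, "chi2_superiority", d.pi_hat)
        t = (p_a - p_b) / math.sqrt(var)
        return TestResult(t, float(stats.norm.sf(t)), 1.0, "chi2_superiority", d.pi_hat)
    if method == "fisher":
        table = [
            [round(d.x_a), round(d.n_a - d.x_a)],
            [round(d.x_b), round(d.n_b - d.x_b)],
        ]
        if pooled in (0.0, 1.0):
            warnings.warn("degenerate margins: all successes or all failures", stacklevel=2)
            return TestResult(0.0, 1.0, 1.0, "fisher_superiority", d.pi_hat)
        _, p = stats.fisher_exact(table, alternative="greater")
        return TestResult(float(d.x_a), float(p), 1.0, "fisher_superiority", d.pi_hat)
    raise ValueError(f"method must be 'chi2' or 'fisher', got {method!r}")


def ak_test(
    counts: TrialCounts,
    delta0: float,
    b_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Bootstrap test of ``H0: Delta <= delta0`` for the Alonzo-Kittelson estimator.

    The five observed cells of each arm are resampled from their empirical
    multinomial distribution; the one-sided p-value is the (add-one
    smoothed) fraction of bootstrap estimates at or below the margin,
    matching the percentile-interval reading of the estimator's confidence
    bound.  Resamples where the estimator is undefined are dropped; if all
    are, an error is raised.  Deterministic under a fixed ``seed``.
    """
    _check_margin(delta0)
    if b_boot < 1:
        raise EstimationError("b_boot must be >= 1")
    base = ak_relative_sensitivity(counts)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = counts.arm_a, counts.arm_b
    cells_a = np.array([a.n_dab, a.n_dab_not, a.n_ndab, a.n_ndab_not, a.n_aneg])
    cells_b = np.array([b.n_dab, b.n_da_not_b, b.n_ndab, b.n_nda_not_b, b.n_bneg])
    res_a = rng.multinomial(a.n_screened, cells_a / a.n_screened, size=b_boot)
    res_b = rng.multinomial(b.n_screened, cells_b / b.n_screened, size=b_boot)
    est = _ak_estimate_from_cells(res_a, res_b)
    est = est[np.isfinite(est)]
    if est.size == 0:
        raise EstimationError("all bootstrap resamples were degenerate")
    p = (1.0 + np.count_nonzero(est <= delta0)) / (est.size + 1.0)
    return TestResult(
        statistic=float(math.log(base.estimate) - math.log(delta0)),
        p_one_sided=float(p),
        margin=delta0,
        method="ak",
        pi_hat=(math.nan, math.nan),
    )
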