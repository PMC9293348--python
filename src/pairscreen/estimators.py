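"""Point estimators of relative accuracy in paired screen-positive trials.

The screen-positive design verifies disease only in first-test positives,
so absolute sensitivity and specificity are unidentifiable; ratios between
the two tests are.  Two estimators of the relative sensitivity
``Delta = Sens_A / Sens_B`` are provided:

* the conditional estimator, a ratio of two conditional proportions among
  verified diseased first-test positives,

  ``Delta_C = (N_DAB^B / N_DB^B) / (N_DAB^A / N_DA^A)``,

  which remains valid when screening uptake differs between arms and is
  related to disease status (the arms may have different screened-population
  prevalences);

* the Alonzo-Kittelson estimator, which pools cells across arms using the
  estimated probability ``gamma`` of being randomized to the A-first arm
  conditional on double positivity, and is unbiased only when the screened
  populations of the two arms are exchangeable.

The conditional relative false-positive fraction uses the same ratio with
nondiseased cells, and the relative detection rate is the classical
unpaired screen-positive contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .counts_model import TrialCounts

__all__ = [
    "EstimationError",
    "EstimateResult",
    "conditional_relative_sensitivity",
    "conditional_relative_fpf",
    "ak_gamma",
    "ak_relative_sensitivity",
    "detection_rate_ratio",
    "katz_ci",
    "ak_bootstrap_ci",
]


class EstimationError(ValueError):
    """An estimator is undefined for the supplied counts."""


@dataclass(frozen=True)
class EstimateResult:
    """A ratio-scale point estimate with the proportions that produced it."""

    estimate: float
    method: str
    numerator_props: tuple[float, float] = field(default=(math.nan, math.nan))
    gamma_hat: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def to_record(self) -> dict:
        record = {"method": self.method, "estimate": self.estimate}
        if self.gamma_hat is not None:
            record["gamma_hat"] = self.gamma_hat
        if self.ci_low is not None:
            record["ci_low"] = self.ci_low
            record["ci_high"] = self.ci_high
        return record


def conditional_relative_sensitivity(counts: TrialCounts) -> EstimateResult:
    """Conditional estimator of the relative sensitivity Sens_A/Sens_B.

    Equals ``pi_A / pi_B`` with ``pi_A = N_DAB^B / N_DB^B`` (fraction of
    verified diseased B-first positives also positive on A) and
    ``pi_B = N_DAB^A / N_DA^A`` (the mirror-image fraction in the A-first
    arm).  Identified under the assumptions that each test's sensitivity
    when given first equals its population sensitivity and that the
    probability of double positivity in diseased subjects does not depend
    on test order.
    """
    n_dbb = counts.arm_b.n_dbb
    n_daa = counts.arm_a.n_daa
    if n_dbb == 0 or n_daa == 0 or counts.arm_a.n_dab == 0 or counts.arm_b.n_dab == 0:
        raise EstimationError(
            "conditional relative sensitivity undefined for zero diseased "
            "numerator or denominator cells; consider the 0.25 zero-cell "
            "correction used in simulation studies"
        )
    pi_a = counts.arm_b.n_dab / n_dbb
    pi_b = counts.arm_a.n_dab / n_daa
    return EstimateResult(
        estimate=pi_a / pi_b,
        method="conditional_rs",
        numerator_props=(pi_a, pi_b),
    )


def conditional_relative_fpf(counts: TrialCounts) -> EstimateResult:
    """Conditional estimator of the relative false-positive fraction.

    The same conditional ratio computed from the nondiseased cells:
    ``(N_D̄AB^B / N_D̄B^B) / (N_D̄AB^A / N_D̄A^A)``.
    """
    n_ndbb = counts.arm_b.n_ndbb
    n_ndaa = counts.arm_a.n_ndaa
    if n_ndbb == 0 or n_ndaa == 0 or counts.arm_a.n_ndab == 0 or counts.arm_b.n_ndab == 0:
        raise EstimationError(
            "conditional relative FPF undefined for zero nondiseased "
            "denominators; consider the 0.25 zero-cell correction"
        )
    pi_a = counts.arm_b.n_ndab / n_ndbb
    pi_b = counts.arm_a.n_ndab / n_ndaa
    return EstimateResult(
        estimate=pi_a / pi_b,
        method="conditional_rfpf",
        numerator_props=(pi_a, pi_b),
    )


def ak_gamma(counts: TrialCounts) -> float:
    """Estimated probability of being in the A-first arm given not double
    positive: ``(N_A - N_AB^A) / (N - N_AB)``.

    Used by the Alonzo-Kittelson estimator to weight the discordant
    diseased cells; assumed not to depend on disease status.
    """
    denom = counts.n_total - counts.n_ab_total
    if denom <= 0:
        raise EstimationError("gamma undefined: no subjects outside the double-positive cell")
    return (counts.arm_a.n_screened - counts.arm_a.n_ab) / denom


def ak_relative_sensitivity(counts: TrialCounts) -> EstimateResult:
    """Alonzo-Kittelson estimator of the relative sensitivity.

    ``(N_DAB^A + N_DAB^B + N_DAB̄^A / gamma) /
    (N_DAB^A + N_DAB^B + N_DĀB^B / (1 - gamma))``.

    Valid when the screened populations in both arms have the same test
    outcome probabilities (no disease-related differential uptake).
    """
    gamma = ak_gamma(counts)
    if not 0.0 < gamma < 1.0:
        raise EstimationError(f"gamma ({gamma}) outside (0, 1); estimator undefined")
    shared = counts.arm_a.n_dab + counts.arm_b.n_dab
    numer = shared + counts.arm_a.n_dab_not / gamma
    denom = shared + counts.arm_b.n_da_not_b / (1.0 - gamma)
    if denom == 0:
        raise EstimationError("Alonzo-Kittelson denominator is zero")
    return EstimateResult(
        estimate=numer / denom,
        method="alonzo_kittelson",
        gamma_hat=gamma,
    )


def detection_rate_ratio(
    counts: TrialCounts | None = None,
    screened_a: int | None = None,
    screened_b: int | None = None,
    *,
    detected_a: int | None = None,
    detected_b: int | None = None,
) -> EstimateResult:
    """Relative detection rate of arm A versus arm B.

    ``(detected_a / screened_a) / (detected_b / screened_b)``.  Detected
    cases default to the verified diseased first-test positives in each
    arm (``N_DA^A``, ``N_DB^B``); pass explicit ``detected_*`` when the
    case counts include subjects outside the paired analysis (as in the
    IMPROVE report, where 73 and 45 CIN3+ cases among all screened women
    include those without paired results).
    """
    if detected_a is None or detected_b is None:
        if counts is None:
            raise EstimationError("need either counts or explicit detected_a/detected_b")
        detected_a = counts.arm_a.n_daa if detected_a is None else detected_a
        detected_b = counts.arm_b.n_dbb if detected_b is None else detected_b
    if screened_a is None or screened_b is None:
        if counts is None:
            raise EstimationError("need screened totals")
        screened_a = counts.arm_a.n_screened if screened_a is None else screened_a
        screened_b = counts.arm_b.n_screened if screened_b is None else screened_b
    if screened_a <= 0 or screened_b <= 0 or detected_b <= 0:
        raise EstimationError("detection rate ratio undefined for zero denominators")
    rate_a = detected_a / screened_a
    rate_b = detected_b / screened_b
    return EstimateResult(
        estimate=rate_a / rate_b,
        method="detection_ratio",
        numerator_props=(rate_a, rate_b),
    )


def katz_ci(counts: TrialCounts, level: float = 0.95) -> EstimateResult:
    """Conditional relative sensitivity with a Katz log-ratio interval.

    The two conditional proportions come from independent binomial samples,
    so the standard error of ``log Delta_C`` is
    ``sqrt((1-pi_A)/(pi_A n_A) + (1-pi_B)/(pi_B n_B))`` with
    ``n_A = N_DB^B`` and ``n_B = N_DA^A``.
    """
    base = conditional_relative_sensitivity(counts)
    pi_a, pi_b = base.numerator_props
    n_a = counts.arm_b.n_dbb
    n_b = counts.arm_a.n_daa
    if pi_a == 1.0 and pi_b == 1.0:
        raise EstimationError("Katz interval degenerate: both proportions are 1")
    se = math.sqrt((1 - pi_a) / (pi_a * n_a) + (1 - pi_b) / (pi_b * n_b))
    z = stats.norm.ppf(0.5 + level / 2)
    log_est = math.log(base.estimate)
    return EstimateResult(
        estimate=base.estimate,
        method=base.method,
        numerator_props=base.numerator_props,
        ci_low=math.exp(log_est - z * se),
        ci_high=math.exp(log_est + z * se),
    )


def _ak_estimate_from_cells(cells_a: np.ndarray, cells_b: np.ndarray) -> np.ndarray:
    """Vectorized Alonzo-Kittelson estimate from (..., 5) per-arm cell arrays.

    Cell order follows the container field order.  Replicates where any of
    the four diseased first-positive cells is zero get 0.25 added to each
    of those four cells; replicates with an undefined gamma or denominator
    come back as NaN.
    """
    dab_a = cells_a[..., 0].astype(float)
    dabn_a = cells_a[..., 1].astype(float)
    dab_b = cells_b[..., 0].astype(float)
    danb_b = cells_b[..., 1].astype(float)
    need = (dab_a == 0) | (dabn_a == 0) | (dab_b == 0) | (danb_b == 0)
    dab_a = dab_a + 0.25 * need
    dabn_a = dabn_a + 0.25 * need
    dab_b = dab_b + 0.25 * need
    danb_b = danb_b + 0.25 * need

    n_a = cells_a.sum(axis=-1)
    n_b = cells_b.sum(axis=-1)
    n_ab_a = cells_a[..., 0] + cells_a[..., 2]
    n_ab = n_ab_a + cells_b[..., 0] + cells_b[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = (n_a - n_ab_a) / (n_a + n_b - n_ab)
        shared = dab_a + dab_b
        est = (shared + dabn_a / gamma) / (shared + danb_b / (1.0 - gamma))
    est = np.where((gamma > 0) & (gamma < 1), est, np.nan)
    return est


def ak_bootstrap_ci(
    counts: TrialCounts,
    level: float = 0.95,
    b_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> EstimateResult:
    """Alonzo-Kittelson estimate with a nonparametric bootstrap interval.

    A closed-form variance for ``log Delta_AK`` is not implemented here;
    instead the five observed cells of each arm are resampled from their
    empirical multinomial distribution (``b_boot`` resamples), and a
    percentile interval on the log scale is returned.  Deterministic under
    a fixed ``seed``.
    """
    if b_boot < 1:
        raise EstimationError("b_boot must be >= 1")
    base = ak_relative_sensitivity(counts)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = counts.arm_a
    b = counts.arm_b
    cells_a = np.array([a.n_dab, a.n_dab_not, a.n_ndab, a.n_ndab_not, a.n_aneg])
    cells_b = np.array([b.n_dab, b.n_da_not_b, b.n_ndab, b.n_nda_not_b, b.n_bneg])
    res_a = rng.multinomial(a.n_screened, cells_a / a.n_screened, size=b_boot)
    res_b = rng.multinomial(b.n_screened, cells_b / b.n_screened, size=b_boot)
    est = _ak_estimate_from_cells(res_a, res_b)
    est = est[np.isfinite(est) & (est > 0)]
    if est.size == 0:
        raise EstimationError("all bootstrap resamples were degenerate")
    lo, hi = np.quantile(np.log(est), [0.5 - level / 2, 0.5 + level / 2])
    return EstimateResult(
        estimate=base.estimate,
        method=base.method,
        gamma_hat=base.gamma_hat,
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
    )
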