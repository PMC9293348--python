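"""Simulation of randomized paired screen-positive trials.

One simulated trial draws, independently per arm, a single multinomial over
the five observable cells (the four disease x second-test categories among
first-test positives, plus first-test negatives).  The cell probabilities
are assembled from:

* the screened-population disease prevalence of the arm (arm B's equals
  ``prev_ratio`` times arm A's, which is how disease-related differential
  uptake enters the data-generating mechanism),
* the marginal sensitivities and specificities of the two tests, and
* within-subject dependence between the tests, induced separately in
  diseased and nondiseased subjects through an odds ratio: the joint
  double-positive probability is the Plackett joint, the unique 2x2
  distribution with the given margins and odds ratio.

Withdrawal is deterministic: an arm with uptake ``u`` screens
``round(m_per_arm * u)`` of its randomized subjects.  Second-test and
verification results after a positive first test are always complete
(missing at random would leave all estimators unchanged in expectation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .counts_model import ArmFirstA, ArmFirstB, TrialCounts

__all__ = [
    "ScenarioConfig",
    "ArmCellProbs",
    "joint_from_margins_or",
    "arm_cell_probs",
    "simulate_trial",
    "simulate_trial_cells",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Full data-generating parameterization of one simulated trial setting.

    Defaults follow the reference simulation protocol: 5000 randomized per
    arm, screened prevalence 0.01 in arm A with equal prevalence in arm B,
    standard-test sensitivity 0.95, equal sensitivities (``rel_sens`` = 1),
    both specificities 0.95, conditional independence between the tests
    (odds ratios 1), and perfect uptake in both arms.
    """

    m_per_arm: int = 5000
    prev_a: float = 0.01
    prev_ratio: float = 1.0
    sens_b: float = 0.95
    rel_sens: float = 1.0
    spec_a: float = 0.95
    spec_b: float = 0.95
    or_d: float = 1.0
    or_nd: float = 1.0
    uptake_a: float = 1.0
    uptake_b: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m_per_arm < 0:
            raise ValueError("m_per_arm must be >= 0")
        if self.rel_sens * self.sens_b > 1.0 + 1e-12:
            raise ValueError("rel_sens * sens_b must not exceed 1")
        for name in ("sens_b", "spec_a", "spec_b", "uptake_a", "uptake_b"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("prev_a", "prev_ratio", "rel_sens", "or_d", "or_nd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.prev_a <= 1.0 or not 0.0 <= self.prev_b <= 1.0:
            raise ValueError("screened prevalences must lie in [0, 1]")
        if self.or_d <= 0 or self.or_nd <= 0:
            raise ValueError("odds ratios must be > 0")

    @property
    def sens_a(self) -> float:
        """Sensitivity of the new test, ``rel_sens * sens_b``."""
        return min(self.rel_sens * self.sens_b, 1.0)

    @property
    def prev_b(self) -> float:
        """Screened-population prevalence in arm B, ``prev_ratio * prev_a``."""
        return self.prev_ratio * self.prev_a

    def to_mapping(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class ArmCellProbs:
    """Probabilities of the five observable cells of one arm (sum to 1)."""

    p_d_pos_pos: float  # diseased, first test +, second test +
    p_d_pos_neg: float  # diseased, first test +, second test -
    p_nd_pos_pos: float
    p_nd_pos_neg: float
    p_first_neg: float

    def as_array(self) -> np.ndarray:
        p = np.array(
            [
                self.p_d_pos_pos,
                self.p_d_pos_neg,
                self.p_nd_pos_pos,
                self.p_nd_pos_neg,
                self.p_first_neg,
            ]
        )
        if np.any(p < -1e-12):
            raise AssertionError(f"negative cell probability: {p}")
        if abs(p.sum() - 1.0) > 1e-12:
            raise AssertionError(f"cell probabilities sum to {p.sum()}, not 1")
        return np.clip(p, 0.0, 1.0)


def joint_from_margins_or(p1: float, p2: float, psi: float) -> float:
    """Double-positive probability of the 2x2 joint with margins ``p1``,
    ``p2`` and odds ratio ``psi`` (Plackett joint).

    Solves ``(psi-1)*p11^2 - (1 + (p1+p2)(psi-1))*p11 + psi*p1*p2 = 0`` for
    the admissible root; ``psi = 1`` gives independence ``p1*p2``.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("margins must lie in [0, 1]")
    if psi <= 0:
        raise ValueError("odds ratio must be > 0")
    if psi == 1.0 or p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return p1 * p2
    s = 1.0 + (p1 + p2) * (psi - 1.0)
    disc = s * s - 4.0 * psi * (psi - 1.0) * p1 * p2
    p11 = (s - np.sqrt(disc)) / (2.0 * (psi - 1.0))
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)
    return float(min(max(p11, lo), hi))


def arm_cell_probs(config: ScenarioConfig, first_test: str) -> ArmCellProbs:
    """Cell probabilities of the arm whose first test is ``"A"`` or ``"B"``.

    The double-positive probability given disease status is shared between
    the arms by construction (it depends only on the margins and the odds
    ratio), which is exactly the identifying order-invariance assumption
    of the conditional estimator.
    """
    p11_d = joint_from_margins_or(config.sens_a, config.sens_b, config.or_d)
    fpf_a = 1.0 - config.spec_a
    fpf_b = 1.0 - config.spec_b
    p11_nd = joint_from_margins_or(fpf_a, fpf_b, config.or_nd)
    if first_test == "A":
        rho = config.prev_a
        first_sens, first_fpf = config.sens_a, fpf_a
    elif first_test == "B":
        rho = config.prev_b
        first_sens, first_fpf = config.sens_b, fpf_b
    else:
        raise ValueError(f"first_test must be 'A' or 'B', got {first_test!r}")
    return ArmCellProbs(
        p_d_pos_pos=rho * p11_d,
        p_d_pos_neg=rho * (first_sens - p11_d),
        p_nd_pos_pos=(1.0 - rho) * p11_nd,
        p_nd_pos_neg=(1.0 - rho) * (first_fpf - p11_nd),
        p_first_neg=1.0 - rho * first_sens - (1.0 - rho) * first_fpf,
    )


def simulate_trial_cells(
    config: ScenarioConfig, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``reps`` trials at once; returns ``(cells_a, cells_b)`` of shape
    ``(reps, 5)`` in the container field order.

    The per-arm screened totals are ``round(m_per_arm * uptake)``.
    """
    n_a = round(config.m_per_arm * config.uptake_a)
    n_b = round(config.m_per_arm * config.uptake_b)
    p_a = arm_cell_probs(config, "A").as_array()
    p_b = arm_cell_probs(config, "B").as_array()
    cells_a = rng.multinomial(n_a, p_a / p_a.sum(), size=reps)
    cells_b = rng.multinomial(n_b, p_b / p_b.sum(), size=reps)
    return cells_a, cells_b


def simulate_trial(
    config: ScenarioConfig, rng: np.random.Generator | int | None = None
) -> TrialCounts:
    """Simulate one trial; deterministic under a fixed seed.

    When ``rng`` is omitted, ``config.seed`` initializes the generator.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    cells_a, cells_b = simulate_trial_cells(config, 1, rng)
    ca = [int(v) for v in cells_a[0]]
    cb = [int(v) for v in cells_b[0]]
    arm_a = ArmFirstA(
        n_dab=ca[0], n_dab_not=ca[1], n_ndab=ca[2], n_ndab_not=ca[3],
        n_aneg=ca[4], n_screened=sum(ca),
    )
    arm_b = ArmFirstB(
        n_dab=cb[0], n_da_not_b=cb[1], n_ndab=cb[2], n_nda_not_b=cb[3],
        n_bneg=cb[4], n_screened=sum(cb),
    )
    return TrialCounts(arm_a=arm_a, arm_b=arm_b, m_a=config.m_per_arm, m_b=config.m_per_arm)
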