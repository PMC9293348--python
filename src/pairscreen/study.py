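"""Monte-Carlo studies of empirical type I error, power, bias and coverage.

Grids are factorial over the scenario parameters.  Each grid cell draws its
replicates in one vectorized pass (a single batched multinomial per arm),
applies the zero-cell correction, evaluates the requested tests on the
whole replicate batch, and records the empirical rejection fraction with
its Monte-Carlo standard error.  Per-cell random streams are derived from
the root seed and a stable hash of the cell's parameters, so results do
not depend on the order in which cells are run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import _ak_estimate_from_cells
from .nitests import TwoBinomialData, _lr_core, _lr_pvalue, _score_core, _wald_core
from .simulator import ScenarioConfig, simulate_trial_cells

__all__ = [
    "GridSpec",
    "StudySummary",
    "zero_cell_adjust",
    "run_rejection_grid",
    "run_estimator_study",
    "summarize",
]

logger = logging.getLogger("pairscreen")

#: relative sensitivity under the alternative, by margin (reference protocol:
#: 1 for noninferiority margins, 1.05 for the superiority margin)
ALTERNATIVE_REL_SENS = {0.90: 1.0, 0.95: 1.0, 1.0: 1.05}


@dataclass(frozen=True)
class GridSpec:
    """Factorial grid of scenario settings for a Monte-Carlo study.

    Default levels follow the reference simulation protocol; ``reps``
    defaults to 2000 for desk-scale runs (the full protocol uses 10000).
    """

    m_per_arm: Sequence[int] = (5000,)
    prev_a: Sequence[float] = (0.01,)
    prev_ratio: Sequence[float] = (1.0,)
    sens_b: Sequence[float] = (0.95,)
    specificity: Sequence[float] = (0.90, 0.95, 0.99)
    odds_ratio: Sequence[float] = (1.0, 2.0, 5.0)
    margins: Sequence[float] = (0.90, 0.95, 1.0)
    uptake_a: float = 1.0
    uptake_b: float = 1.0
    reps: int = 2000
    seed: int = 0
    tests: Sequence[str] = ("wald", "score", "lr")
    alpha: float = 0.05
    ak_boot: int = 500

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for d0 in self.margins:
            if not 0.0 < d0 <= 1.0:
                raise ValueError(f"margins must lie in (0, 1], got {d0}")
        unknown = set(self.tests) - {"wald", "score", "lr", "ak"}
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")

    def settings(self) -> Iterable[dict]:
        """All grid cells as parameter dicts (margin included)."""
        for m, prev, ratio, sb, sp, psi, d0 in product(
            self.m_per_arm, self.prev_a, self.prev_ratio, self.sens_b,
            self.specificity, self.odds_ratio, self.margins,
        ):
            yield {
                "m_per_arm": m,
                "prev_a": prev,
                "prev_ratio": ratio,
                "sens_b": sb,
                "specificity": sp,
                "odds_ratio": psi,
                "margin": d0,
                "uptake_a": self.uptake_a,
                "uptake_b": self.uptake_b,
            }


@dataclass(frozen=True)
class StudySummary:
    """Per-setting records of a Monte-Carlo study."""

    table: pd.DataFrame
    reps: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def zero_cell_adjust(d: TwoBinomialData) -> TwoBinomialData:
    """Zero-cell correction of the simulation protocol.

    If any of the four conditional cells (``x_a``, ``n_a - x_a``, ``x_b``,
    ``n_b - x_b``) is zero, add 0.25 to each of the four (both sample sizes
    grow by 0.5); otherwise return the data unchanged.
    """
    cells = (d.x_a, d.n_a - d.x_a, d.x_b, d.n_b - d.x_b)
    if min(cells) > 0:
        return d
    return TwoBinomialData(
        x_a=d.x_a + 0.25, n_a=d.n_a + 0.5, x_b=d.x_b + 0.25, n_b=d.n_b + 0.5
    )


def _zero_cell_adjust_vec(x_a, n_a, x_b, n_b):
    """Vectorized zero-cell correction on float arrays."""
    need = (x_a == 0) | (n_a - x_a == 0) | (x_b == 0) | (n_b - x_b == 0)
    bump = 0.25 * need
    return x_a + bump, n_a + 2 * bump, x_b + bump, n_b + 2 * bump


def _setting_rng(root_seed: int, params: dict, label: str) -> np.random.Generator:
    """Independent, order-invariant random stream for one grid cell."""
    payload = json.dumps({"label": label, **params}, sort_keys=True).encode()
    digest = hashlib.sha256(payload).digest()
    key = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([root_seed % (2**31), key]))


def _conditional_cells(cells_a: np.ndarray, cells_b: np.ndarray):
    """Adjusted two-binomial samples from per-arm cell matrices."""
    x_b = cells_a[:, 0].astype(float)  # N_DAB^A
    n_b = (cells_a[:, 0] + cells_a[:, 1]).astype(float)  # N_DA^A
    x_a = cells_b[:, 0].astype(float)  # N_DAB^B
    n_a = (cells_b[:, 0] + cells_b[:, 1]).astype(float)  # N_DB^B
    return _zero_cell_adjust_vec(x_a, n_a, x_b, n_b)


def _ak_reject_vec(
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    delta0: float,
    alpha: float,
    b_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap Alonzo-Kittelson rejection indicator per replicate (NaN if
    the bootstrap is fully degenerate for a replicate)."""
    reps = cells_a.shape[0]
    n_a = int(cells_a[0].sum())
    n_b = int(cells_b[0].sum())
    p_a = cells_a / n_a
    p_b = cells_b / n_b
    res_a = rng.multinomial(n_a, p_a[:, None, :], size=(reps, b_boot))
    res_b = rng.multinomial(n_b, p_b[:, None, :], size=(reps, b_boot))
    est = _ak_estimate_from_cells(res_a, res_b)  # (reps, b_boot)
    valid = np.isfinite(est)
    n_valid = valid.sum(axis=1)
    n_low = np.where(valid, est <= delta0, False).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = (1.0 + n_low) / (n_valid + 1.0)
    reject = (p < alpha).astype(float)
    reject[n_valid == 0] = np.nan
    return reject


def run_rejection_grid(grid: GridSpec, hypothesis: str = "null_boundary") -> StudySummary:
    """Empirical rejection rates of the requested tests over the grid.

    Under ``hypothesis="null_boundary"`` the data-generating relative
    sensitivity sits exactly on the margin (``Sens_A = delta0 * Sens_B``),
    so rejection rates estimate the type I error.  Under ``"alternative"``
    it is 1 for noninferiority margins and 1.05 for the superiority margin,
    and rejection rates estimate power.  Replicates where a test is
    undefined are excluded from that test's denominator and counted in
    ``n_excluded``.
    """
    if hypothesis not in ("null_boundary", "alternative"):
        raise ValueError(f"hypothesis must be 'null_boundary' or 'alternative', got {hypothesis!r}")
    rows = []
    for params in grid.settings():
        d0 = params["margin"]
        if hypothesis == "null_boundary":
            rel_sens = d0
        else:
            rel_sens = ALTERNATIVE_REL_SENS.get(d0, 1.0)
        config = ScenarioConfig(
            m_per_arm=params["m_per_arm"],
            prev_a=params["prev_a"],
            prev_ratio=params["prev_ratio"],
            sens_b=params["sens_b"],
            rel_sens=rel_sens,
            spec_a=params["specificity"],
            spec_b=params["specificity"],
            or_d=params["odds_ratio"],
            or_nd=params["odds_ratio"],
            uptake_a=params["uptake_a"],
            uptake_b=params["uptake_b"],
        )
        rng = _setting_rng(grid.seed, params, f"rejection:{hypothesis}")
        cells_a, cells_b = simulate_trial_cells(config, grid.reps, rng)
        x_a, n_a, x_b, n_b = _conditional_cells(cells_a, cells_b)
        for test in grid.tests:
            if test == "wald":
                stat = _wald_core(x_a, n_a, x_b, n_b, d0)
                reject = np.where(np.isnan(stat), np.nan, stats.norm.sf(stat) < grid.alpha)
            elif test == "score":
                stat = _score_core(x_a, n_a, x_b, n_b, d0)
                reject = np.where(np.isnan(stat), np.nan, stats.norm.sf(stat) < grid.alpha)
            elif test == "lr":
                stat = _lr_core(x_a, n_a, x_b, n_b, d0)
                reject = (_lr_pvalue(stat) < grid.alpha).astype(float)
            else:  # ak
                reject = _ak_reject_vec(cells_a, cells_b, d0, grid.alpha, grid.ak_boot, rng)
            n_excluded = int(np.isnan(reject).sum())
            if n_excluded:
                logger.warning(
                    "%d/%d replicates excluded for %s at %s", n_excluded, grid.reps, test, params
                )
            n_used = grid.reps - n_excluded
            rate = float(np.nansum(reject) / n_used) if n_used else float("nan")
            rows.append(
                {
                    **params,
                    "hypothesis": hypothesis,
                    "rel_sens_true": rel_sens,
                    "test": test,
                    "rejection_rate": rate,
                    "mc_se": float(np.sqrt(rate * (1 - rate) / n_used)) if n_used else float("nan"),
                    "n_excluded": n_excluded,
                }
            )
    meta = {"hypothesis": hypothesis, "alpha": grid.alpha}
    if "ak" in grid.tests:
        meta["ak_boot"] = grid.ak_boot
    return StudySummary(table=pd.DataFrame(rows), reps=grid.reps, seed=grid.seed, metadata=meta)


def run_estimator_study(grid: GridSpec, true_delta: float = 1.0) -> StudySummary:
    """Bias, precision and 95% CI coverage of the two estimators.

    Per setting: replicate means and SDs of the conditional and
    Alonzo-Kittelson relative-sensitivity estimates (zero-cell corrected),
    plus the empirical coverage of the Katz log-ratio interval for the
    conditional estimator, all against the data-generating ``true_delta``
    (the grid's margins are ignored here).
    """
    if not true_delta > 0:
        raise ValueError("true_delta must be > 0")
    rows = []
    base = replace(grid, margins=(1.0,))
    for params in base.settings():
        params = {k: v for k, v in params.items() if k != "margin"}
        config = ScenarioConfig(
            m_per_arm=params["m_per_arm"],
            prev_a=params["prev_a"],
            prev_ratio=params["prev_ratio"],
            sens_b=params["sens_b"],
            rel_sens=true_delta,
            spec_a=params["specificity"],
            spec_b=params["specificity"],
            or_d=params["odds_ratio"],
            or_nd=params["odds_ratio"],
            uptake_a=params["uptake_a"],
            uptake_b=params["uptake_b"],
        )
        rng = _setting_rng(grid.seed, params, "estimator")
        cells_a, cells_b = simulate_trial_cells(config, grid.reps, rng)
        x_a, n_a, x_b, n_b = _conditional_cells(cells_a, cells_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            pi_a = x_a / n_a
            pi_b = x_b / n_b
            delta_c = pi_a / pi_b
            se_log = np.sqrt((1 - pi_a) / (pi_a * n_a) + (1 - pi_b) / (pi_b * n_b))
            log_dc = np.log(delta_c)
            z = stats.norm.ppf(0.975)
            covered = (np.abs(log_dc - np.log(true_delta)) <= z * se_log).astype(float)
        delta_ak = _ak_estimate_from_cells(cells_a, cells_b)
        ok_c = np.isfinite(delta_c)
        ok_ak = np.isfinite(delta_ak)
        n_c = int(ok_c.sum())
        n_ak = int(ok_ak.sum())
        rows.append(
            {
                **params,
                "true_delta": true_delta,
                "mean_conditional": float(delta_c[ok_c].mean()),
                "sd_conditional": float(delta_c[ok_c].std(ddof=1)),
                "mc_se_conditional": float(delta_c[ok_c].std(ddof=1) / np.sqrt(n_c)),
                "coverage_katz": float(covered[ok_c & np.isfinite(covered)].mean()),
                "mean_ak": float(delta_ak[ok_ak].mean()),
                "sd_ak": float(delta_ak[ok_ak].std(ddof=1)),
                "mc_se_ak": float(delta_ak[ok_ak].std(ddof=1) / np.sqrt(n_ak)),
                "n_excluded_conditional": grid.reps - n_c,
                "n_excluded_ak": grid.reps - n_ak,
            }
        )
    return StudySummary(
        table=pd.DataFrame(rows), reps=grid.reps, seed=grid.seed,
        metadata={"true_delta": true_delta},
    )


def summarize(
    summary: StudySummary,
    stat: str = "max",
    by: Sequence[str] = ("prev_a", "prev_ratio", "test"),
) -> pd.DataFrame:
    """Aggregate rejection rates across grid cells.

    ``stat`` is ``"max"``, ``"median"`` or ``"quartiles"``; grouping
    defaults to the axes used in the reference study's summary figures.
    """
    if summary.table.empty:
        raise ValueError("empty study summary")
    by = [c for c in by if c in summary.table.columns]
    grouped = summary.table.groupby(list(by))["rejection_rate"]
    if stat == "max":
        return grouped.max().reset_index()
    if stat == "median":
        return grouped.median().reset_index()
    if stat == "quartiles":
        out = grouped.quantile([0.25, 0.5, 0.75]).unstack()
        out.columns = ["q25", "median", "q75"]
        return out.reset_index()
    raise ValueError(f"stat must be 'max', 'median' or 'quartiles', got {stat!r}")


def plot_rejection_rates(summary: StudySummary, path: str | Path) -> None:
    """Boxplot of per-cell rejection rates grouped by test, written to ``path``.

    A quick visual check of level control / power across a grid; the 5%
    nominal level is drawn as a reference line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if summary.table.empty:
        raise ValueError("empty study summary")
    groups = [
        (test, sub.rejection_rate.to_numpy())
        for test, sub in summary.table.groupby("test")
    ]
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(groups), 4))
    ax.boxplot([g[1] for g in groups], tick_labels=[g[0] for g in groups], whis=(0, 100))
    ax.axhline(0.05, color="grey", linestyle="--", linewidth=1)
    ax.set_ylabel("empirical rejection rate")
    ax.set_xlabel("test")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
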