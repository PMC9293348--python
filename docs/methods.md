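# Methods

This note documents the statistical model behind `pairscreen`, the choices
made where the design was genuinely open, and what the simulation studies
do and do not establish.

## Design and data model

In a randomized paired screen-positive trial, `M_A` subjects are randomized
to receive the new screening test A first and `M_B` to receive the standard
test B first. Only first-test positives receive the other test and the
gold-standard verification, so each arm contributes five observable cells:
the four disease × second-test categories among first-test positives, and
the count of first-test negatives. `N_A` and `N_B` count subjects with
*complete follow-up*; subjects positive on the first test whose second test
or verification is missing must be excluded before analysis, under a
missing-at-random assumption for that (post-positive) missingness. The
first test itself may be missing *not* at random — that is the whole point:
uptake may depend on arm and on disease risk. Counts are integers at the
I/O boundary; the fractional 0.25 zero-cell correction (below) belongs to
the analysis layer, not the data model.

## Estimators

**Conditional estimator.** Writing `π_A = P(A+ | B+, D+)` and
`π_B = P(B+ | A+, D+)`, three assumptions identify the relative sensitivity
`Δ = Sens_A/Sens_B = π_A/π_B`: (i) each test's sensitivity when
administered first equals its population sensitivity; (ii) the probability
of double positivity among diseased subjects does not depend on the order
of administration; (iii) MAR for everything after a positive first test.
Nothing requires the two arms' screened populations to have the same
disease prevalence, which is what makes `Δ̂_C = π̂_A/π̂_B` robust to
disease-related differential uptake. The analogous ratio over verified
*non*diseased cells estimates the relative false-positive fraction.

**Alonzo–Kittelson estimator.** Pools discordant diseased cells across
arms, weighting by `γ̂ = (N_A − N_AB^A)/(N − N_AB)`, the estimated
probability of being in the A-first arm. Valid when the two screened
populations are exchangeable; biased when uptake is disease-related (the
estimator-bias study quantifies this). Its interval and test here use a
nonparametric bootstrap — per-arm multinomial resampling of the five
observed cells, percentile interval on the log scale — because no
closed-form variance is implemented; the bootstrap is clearly labelled in
results and a formula-based variant can be slotted in later.

**Confidence intervals.** The interval for `log Δ̂_C` uses the Katz
two-independent-binomial standard error
`√((1−π̂_A)/(π̂_A n_A) + (1−π̂_B)/(π̂_B n_B))`. This is a choice, not a
derived necessity; its empirical coverage is checked by the estimator
study (≈0.95 under equal uptake at the reference settings).

## Tests

All tests are one-sided for `H0: π_A/π_B ≤ δ0` at level α = 0.05 by
default, margin `δ0 ∈ (0, 1]`.

* **Wald**: unrestricted-variance statistic, upper-normal p.
* **Score** (Miettinen–Nurminen): variance at the constrained MLE under
  `π_A = δ0 π_B` times the finite-sample factor `(n_A+n_B)/(n_A+n_B−1)`.
  The constrained MLE is the closed-form quadratic root
  `π̃_B = (−b − √(b²−4ac))/(2a)` with `a = δ0(n_A+n_B)`,
  `b = −(δ0 n_A + x_A + n_B + δ0 x_B)`, `c = x_A + x_B`; it is verified in
  the test suite against numerical maximization of the constrained
  conditional log-likelihood to 1e-6 on random tables.
* **Likelihood ratio**: `T_LR = −2(ℓ_C(π̃) − ℓ_C(π̂))` when
  `π̂_A − δ0 π̂_B ≥ 0`, else 0; because the null hypothesis is a boundary,
  the null distribution is the chi-bar-square mixture `½χ²₀ + ½χ²₁`. At
  `T_LR = 0` the reported p is 1 (the limit from the right is 0.5 — a
  documented discontinuity; the conservative value is reported).
* **Superiority** (δ0 = 1): signed square root of the Pearson chi-square
  statistic with an upper-normal p (no continuity correction, keeping
  parity with the uncorrected score machinery), and the plain one-sided
  Fisher exact conditional tail (no mid-p). Degenerate margins return
  p = 1 with a warning.
* **Alonzo–Kittelson test**: one-sided bootstrap percentile test, p =
  (1 + #{Δ̂* ≤ δ0})/(B+1), add-one smoothed; degenerate resamples are
  dropped, and an error is raised only if all are degenerate.

On the packaged worked example (margin 0.9) the Wald, score and LR
p-values are 0.0128, 0.0550 and 0.0376. The score value deserves a note:
the published reanalysis of the same counts reports 0.043 for the score
test, which the score formulas as printed (and as implemented here,
cross-checked term by term) do not reproduce — they give 0.055. The Wald
and LR values do reproduce exactly. The formulas are implemented as
printed; no adjustment was made to match the 0.043.

## Simulator

One trial is two independent multinomials, one per arm, over the five
observable cells. Cell probabilities combine the arm's screened-population
prevalence, the tests' margins (sensitivities / false-positive fractions)
and a within-subject dependence between tests induced separately in
diseased and nondiseased subjects by an odds ratio ψ. The double-positive
probability is the Plackett joint — the unique 2×2 joint with the given
margins and odds ratio, the admissible root of
`(ψ−1)p11² − [1+(p1+p2)(ψ−1)]p11 + ψ p1 p2 = 0` (independence `p1·p2` at
ψ = 1). Because the joint depends only on margins and ψ, the double-positive
probability given disease is the same in both arms — the identifying
order-invariance assumption holds by construction.

Differential uptake is modelled marginally: an arm with uptake `u` screens
`round(m·u)` subjects, and the *screened-population* prevalence of arm B is
set directly as `prev_ratio × prev_a`. No individual-level selection model
is attempted; the reference protocol parameterizes exactly these two
quantities. Second tests and verification after a positive first test are
always complete (the simplest MAR-consistent choice). Specificities of the
two tests are equal within a setting by default (the grid values 0.90,
0.95, 0.99 are read as paired, not crossed); both can be overridden.

Defaults are the reference study conditions: 5000 randomized per arm,
prevalence 0.01 (arm-B ratio in {0.5, 0.75, 1, 1.25} where varied),
`Sens_B` 0.95 (0.75/0.85 where varied), margins {0.90, 0.95, 1}, odds
ratios {1, 2, 5}, 0% withdrawal in arm A and 20% in arm B for the
differential settings, one-sided α = 5%.

## Monte-Carlo studies

Each grid cell draws all replicates in one vectorized multinomial pass and
evaluates all tests on the batch. The **zero-cell correction** of the
reference protocol is applied per replicate: when any of the four
conditional cells (`N_DAB^A`, `N_DAB̄^A`, `N_DAB^B`, `N_DĀB^B`) is zero,
0.25 is added to each of the four. Replicates where a test is still
undefined are excluded from that test's denominator and counted in
`n_excluded`. Per-cell random streams are derived from the root seed and a
SHA-256 hash of the cell's parameters, so results are independent of the
order in which cells run. Under the alternative hypothesis the
data-generating relative sensitivity is 1 for margins 0.90/0.95 and 1.05
for margin 1. The default replicate count in the desk-scale configuration
is 2000 per cell (the full protocol size is 10 000); the A&K bootstrap
inside grids uses B = 500 resamples, flagged in the summary metadata.

What the studies show at the reference conditions (see
`tests/test_acceptance.py` and `scripts/acceptance.py`, which compute all
of these at run time):

* **Perfect uptake, prevalence 0.01, Sens_B 0.95, 5000/arm**: the Wald and
  bootstrap-A&K tests exceed the nominal 5% level, with a grid maximum
  around 7.5–8%; the score test is conservative in every cell.
* **20% arm-B withdrawal, prevalence ratio 0.5**: the Wald test's type I
  error inflates severely (median ≈ 12% across the grid, worst cells ≈
  14%); score remains conservative.
* **LR level**: exact enumeration over the binomial hierarchy (no Monte
  Carlo) shows the LR test's true level reaches ≈ 6.0% in the worst
  margin-0.95 cells of both grids — mildly above nominal at these very
  small event counts (≈ 45 diseased first-test positives per arm). A
  formalization requiring every cell to sit within three Monte-Carlo
  standard errors of 5% therefore fails for the LR test for typical seeds,
  and the corresponding acceptance checks are expected to be red; this is
  a property of the chi-bar-square LR test at tiny samples, not an
  implementation artifact. When strict level control matters at low
  prevalence, use the score test.
* **Bias**: under equal uptake/prevalence both estimators are unbiased
  within Monte-Carlo error; under differential uptake the A&K estimator's
  mean departs from the true Δ by many Monte-Carlo standard errors (≈ +3%
  at ratio 0.5) while the conditional estimator does not. Katz-interval
  coverage is ≈ 0.95 under equal uptake.

Passing these studies says nothing about real-data features the generator
does not emulate: covariate-driven individual uptake, informative
missingness after a positive first test, verification error in the gold
standard, or clustering.

## Sample-size planning

Planning proceeds in three steps. (1) The anticipated `Sens_B`, relative
sensitivity `Δ1` and diseased odds ratio ψ give the design proportions
`π_A = p11/Sens_B`, `π_B = p11/Sens_A` (so `π_A/π_B = Δ1` exactly).
(2) The required events solve the one-sided normal-approximation power
equation `n_A = (z_{1−α}σ0 + z_{power}σ1)²/(π_A − δ0 π_B)²` with
`σ1² = π_A(1−π_A) + δ0²π_B(1−π_B)/κ` at the alternative. Two null-variance
choices are offered for σ0: the margin-constrained MLE limits (the
classical Farrington–Manning form, which sizes the *score* test) and the
alternative itself (the large-sample limit of the Wald denominator, which
sizes the *Wald* test). The two differ materially when proportions are
near 1: at the reference example (π_A = π_B = 0.95, δ0 = 0.9) they give 81
vs 59 events, and simulating at the constrained-form size yields ≈ 88%
Wald power instead of 80%. Since the protocol powers the Wald test,
`randomized_per_arm` defaults to the Wald-variance form (empirical Wald
power ≈ 79% at the returned size, within Monte-Carlo error of target);
`target_test="score"` selects the classical form. (3) Events are inflated
to numbers randomized by each arm's expected event rate per randomized
subject (`uptake × prevalence × sensitivity`); with 1:1 randomization the
event-allocation ratio κ is fixed at the ratio of those rates, and the
binding arm determines `m_per_arm` (ceiling rounding, expectations only —
no variance margin on the number of events).

## Numerical notes and degenerate inputs

* Quadratic discriminants are clamped at zero before the square root
  (roundoff can push an exact zero slightly negative); constrained MLEs
  are clipped to [0, 1].
* `0·log 0` is evaluated as 0 throughout (via `scipy.special.xlogy`).
* Estimators raise `EstimationError` on undefined input (zero
  denominators, γ̂ outside (0,1)) rather than returning NaN; the error
  message points at the zero-cell correction where that is the standard
  remedy.
* Fisher's test requires integer counts; corrected (fractional) data use
  the asymptotic tests.
* The Plackett root is clamped to the Fréchet bounds
  `[max(0, p1+p2−1), min(p1, p2)]`.

## Known limitations

* The A&K test is a bootstrap surrogate, not the original closed-form
  interval; its level tracks the Wald test's in the grids but is not the
  published variant.
* The Wald and LR tests are anti-conservative at very small event counts
  (quantified above); the score test is the safe default for strict level
  control.
* Only aggregated cell counts are ingested; no subject-level data, no
  covariates, no longitudinal safety comparisons, no two-sided or exact
  unconditional (Barnard-type) tests.
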