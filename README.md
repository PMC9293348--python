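# pairscreen

Design and analysis of **randomized paired screen-positive trials** — the
study design used to compare a new screening test A against the standard
test B when disease verification is only ethical/affordable for
screen-positives. Subjects are randomized to receive one test first; only
those positive on their first test receive the other test and the
gold-standard verification. Absolute sensitivity and specificity are
unidentifiable in this design, but their *ratios* between tests are.

The package is aimed at biostatisticians planning or analysing population
screening trials (its worked example is the IMPROVE trial of HPV testing on
self-collected vs provider-collected samples, endpoint CIN3+). Its focus is
the nonblinded setting, where **screening uptake can differ between arms
and be related to disease risk** — e.g. women with a poor screening history
withdrawing more often from the burdensome arm. Classical estimators assume
exchangeable arms and break down there.

## The statistics inside

Writing `π_A = P(A+ | B+, D+)` (fraction of verified diseased,
standard-test-first positives who are also positive on the new test) and
`π_B = P(B+ | A+, D+)` (the mirror image), the **conditional estimator** of
the relative sensitivity Δ = Sens_A/Sens_B is

```
Δ̂_C = (N_DAB^B / N_DB^B) / (N_DAB^A / N_DA^A)  =  π̂_A / π̂_B
```

It conditions on verified disease status, so a difference in
screened-population prevalence between arms cancels out. Because π̂_A and
π̂_B are proportions from two independent binomial samples, the one-sided
noninferiority hypothesis `H0: Δ ≤ δ0` is tested with

* the **Wald** statistic `(π̂_A − δ0 π̂_B) / √V̂` with the unrestricted
  variance,
* the **Miettinen–Nurminen score** statistic, whose variance is evaluated
  at the closed-form constrained MLE under `π_A = δ0 π_B`, and
* the **likelihood-ratio** statistic with the chi-bar-square null
  `½χ²₀ + ½χ²₁` (one-sided boundary hypothesis),

plus one-sided chi-square / Fisher exact tests for superiority (δ0 = 1).
The classical **Alonzo–Kittelson estimator** (with its weighting
probability γ̂ and a bootstrap interval/test) is included for comparison,
along with a trial **simulator** (multinomial cells per arm; between-test
dependence via Plackett joints with given margins and odds ratio),
Monte-Carlo **study runners** for type I error / power / bias / coverage,
and **Farrington–Manning-style sample-size planning** inflated to numbers
randomized by anticipated uptake, prevalence and sensitivity.

## Worked example

```sh
pairscreen analyze --fixture improve --margin 0.9
```

analyses the packaged IMPROVE counts (arm A, self-sampling first: 72
verified CIN3+ among screen-positives with paired results, 69 of them also
positive on the provider test; arm B: 41 verified CIN3+, 39 positive on the
self test). Key lines of the JSON report:

```
"conditional_rs":    {"estimate": 0.9926, "ci_low": 0.9122, "ci_high": 1.0800}
"conditional_rfpf":  {"estimate": 1.0791}
"alonzo_kittelson":  {"estimate": 1.0091, "gamma_hat": 0.5493}
"wald":  {"statistic": 2.2313, "p_one_sided": 0.0128, "margin": 0.9}
"score": {"statistic": 1.5984, "p_one_sided": 0.0550, "margin": 0.9}
"lr":    {"statistic": 3.1646, "p_one_sided": 0.0376, "margin": 0.9}
```

Read: self-sampling's sensitivity for CIN3+ is estimated at 99.3% of
provider-sampling's ((39/41)/(69/72) = 0.993), with the Wald and LR tests
rejecting `H0: Δ ≤ 0.9` at the one-sided 5% level (p = 0.013 and 0.038) —
self-sampling is noninferior at the prespecified margin 0.9. The relative
false-positive fraction is 1.079. The published relative detection rate of
1.33 (73/7643 vs 45/6282, all screened women) itself hints at
disease-related differential uptake, which is why the conditional analysis
is the primary one.

Sample-size planning and simulation grids run from config files:

```sh
pairscreen design   --spec examples/design_example.yaml
pairscreen simulate --grid examples/type1_differential.yaml --out type1.tsv
```

The first prints `{"n_events_a": 59, "n_events_b": 59, "m_per_arm": 6211, ...}`:
59 diseased first-test positives per arm, i.e. about 6211 randomized per
arm at 1% prevalence, 95% standard-test sensitivity and perfect uptake, for
80% Wald-test power at margin 0.9. The second writes a tidy TSV of
empirical rejection rates per grid cell under 20% withdrawal in the
standard-test arm.

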