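# Methods

## Model and procedure

The package simulates two-arm, 1:1-randomized trials with one baseline and
one 6-month-endpoint assessment, scored on a subdomain of an adaptive
behavior instrument. The generative model is bivariate normal on the
ability (GSV) scale: baseline and endpoint scores share a mean μ, an SD σ
and a within-subject correlation ρ; the treatment arm's endpoint mean is
shifted by Δ. Norm-referenced (V-scale) scores are never generated
directly — they are obtained by pushing each simulated GSV back through the
instrument's lookup tables at the participant's own age at that timepoint,
exactly as a real dataset would be scored. Both endpoint scales are then
analyzed from the same simulated datasets, so the power comparison between
scales is paired within scenario.

A scenario fixes four design factors:

| factor | levels | role |
| --- | --- | --- |
| age range | 3–6 y (`[36, 84)` months), 12–16 y (`[144, 204)` months) | which normative bands the sample spans |
| impairment | 1–5 SD below the normative mean (target V-scale 12, 9, 6, 3, 1) | where μ sits on the scale |
| subdomain | the 11 content scales of the table set | which lookup tables apply |
| effect | large (Δ = 0.8σ) or zero (type-I condition) | alternative vs null |

The month interval for an age range of (a, b) years is `[12a, 12(b+1))`,
whose midpoints — 60 and 174 months — are the ages at which the mean chain
is evaluated.

### Generative parameters

* **μ** — midpoint age → the V-scale value for the impairment level → the
  average raw score of that V-scale band (midpoint of the band, rounded
  half-up) → the GSV tabulated for that raw score. When the target band is
  absent at the required age the scenario is infeasible and is skipped with
  a logged reason; this reproduces the behavior of real norm tables, where
  low V-scale values do not exist at ages where a raw score of 0 is not yet
  extreme.
* **σ** — each normative age band overlapping the design range contributes
  an SD from its measurement properties, `SD = SEM/√(1−r)` (classical test
  theory: the SEM is the unreliable share of the population SD), and a mean
  from the μ-chain evaluated at the band's midpoint age. Bands are pooled
  with the mixture variance `σ²_mix = Σ w σ² + [Σ w μ² − (Σ w μ)²]`, with
  weights w proportional to months of overlap. The dispersion-of-means term
  is what makes a wide age range noisier than a narrow one.
* **Δ** — 0.8 σ_mix under the large-effect condition, 0 under the null.
  Using σ_mix (rather than any single band's SD) keeps the standardized
  effect exactly 0.8 by construction.
* **ρ** — 0.8, a compromise between published test-retest correlations for
  the norm-referenced scores (0.69–0.87) and observed 6-month within-person
  ability-score correlations in natural-history data (0.86–0.96).

### Sample size

`required_total_n(0.8, 0.05, 0.90)` uses the normal-approximation two-sample
formula `4(z_{1−α/2}+z_{power})²/d²` rounded up to an even total, giving 66
(the exact-t answer is 68; the normal form is what the planning arithmetic
implies). The baseline covariate reduces the required N by the factor 1−ρ²;
`ancova_adjusted_n(66, 0.8)` even-ceils 66·0.36 = 23.76 to **24**, i.e. 12
per arm.

### Analysis of each replication

Ordinary least squares of endpoint on intercept + arm + baseline; the arm
coefficient's two-sided p-value uses the t distribution with N−3 = 21 df.
The fit is flagged *degenerate* when the design matrix is rank-deficient
(constant baseline, or baseline collinear with arm — relative tolerance
1e-12 on the normal-equations determinant) or the residual sum of squares
is zero to the same relative tolerance (endpoint an exact linear function
of the design, including the all-constant floor case). Power is the
fraction of replications with p < α (strict inequality); degenerate fits
and replications in which an entire arm scores the scale minimum at both
timepoints are coded as failures to reject. Complete-floor classification
is recorded separately from degeneracy because a single floored arm can
still leave an estimable model; both are conservative failures.

The fitting is a closed-form vectorized least squares authored in the
package (a study is ~10⁶ fits; per-fit OLS calls are orders of magnitude
too slow), verified in the tests against an explicit normal-equations solve
and against statsmodels OLS to 1e-9 on the p-value.

### Analytic power cross-check

The residual SD of the ANCOVA is σ√(1−ρ²), so the adjusted standardized
effect is d′ = d/√(1−ρ²) = 1.33 with noncentrality d′√(n/2) on 21 df. The
naive noncentral-t formula ignores that the baseline covariate is *random*:
chance baseline imbalance between arms inflates the arm-coefficient
variance by 1 + F/(N−2) with F ~ F(1, N−2). `ancova_power` integrates the
noncentral-t power over that F distribution; at N = 24 this gives 0.860
where the fixed-covariate formula gives 0.876, and simulation agrees with
the former to Monte-Carlo precision. This is why the empirical GSV power
band sits at 85–86% rather than at the naive 87–88%.

GSV power is *scale-free*: every feasible scenario shares d = 0.8, ρ = 0.8,
N = 24, so its GSV power is the same number regardless of the tables (the
tests verify invariance of GSV p-values under affine rescaling of the
ability metric). All scale-dependent behavior lives in the V-scale arm of
the comparison.

## Randomness and reproducibility

One root seed governs a run. Each scenario gets an independent child stream
keyed by `(root_seed, CRC32(scenario label))`, so results are invariant to
the order in which scenarios execute and to which other scenarios are
present. All replications of a scenario are drawn in one batched call;
`simulate_trial` (the single-dataset API) delegates to the batched path
with `n_reps=1`, so the two can never diverge. Reruns with the same seed
are byte-identical, including the CSV outputs.

## The synthetic tables

The real instrument's raw→GSV and age-banded raw→V-scale tables are
copyrighted, so the package generates structurally faithful stand-ins.

* **Developmental curves.** Median raw score vs age is logistic,
  `m(a) = R/(1+e^{−k(a−a₀)})`, with per-subdomain midpoints a₀ spread from
  24 months (motor- and language-like scales, which saturate early and
  therefore exhibit strong adolescent floors) to 166 months
  (academic-like scales, for which low V-scale bands do not exist at
  preschool ages). Maximum raw scores R are drawn per subdomain in 60–160.
* **V-scale bands.** At each 12-month age band, the raw distribution is
  modelled as N(m(a), s) with s = 0.12R, and band edges are the normal
  quantile cuts of the discrete mean-15/SD-3 scale (upper cut of value v at
  z = (v+0.5−15)/3), rounded, clipped to [0, R] and forced to partition it.
  Narrow bands matter: with wide (36-month) bands, fast-growing subdomains
  shift by ~2 population SDs between adjacent bands and a sample spanning
  two bands scores bimodally; 12-month bands match the granularity real
  norm tables use in childhood.
* **raw→GSV.** A monotone blend of 0.75·linear + 0.25·logit from the GSV
  floor of 10 to a per-subdomain maximum drawn in 110–197. The logit share
  stretches the ability metric at the raw extremes (Rasch-like); the linear
  share keeps the bulk slope near the mean GSV-per-raw slope so one
  normative raw SD spans about one normative GSV SD everywhere. Rounding to
  integer GSVs produces runs of raw scores sharing a GSV, which is what the
  median-raw rule (lower-central value for even runs, keeping raw scores
  integral and conservative near floors) exists to resolve.
* **SEM and reliability.** SEM is drawn per age band inside 2–9 GSV units,
  restricted so the reliability implied by `SEM = SD√(1−r)` — with SD the
  normative within-age GSV SD, 0.12(G_max−10) — lands inside 0.69–0.97.
  Drawing SEM and reliability independently would break the identity
  between the SEM-derived SD and the SD the V-scale bands assume for the
  same population, making the generative sample over- or under-dispersed
  on its own instrument's norms.

What the synthetic tables do **not** emulate: the real instrument's exact
band widths, GSV spacing, age trends in SEM (synthetic SEMs are exchangeable
across bands), or skewed raw-score distributions near the ceiling — the
normal-quantile construction compresses top V-scale bands at saturated
ages, which is one reason V-scale power at the mildest impairment can sit
slightly below the next level (an inversion the source data also shows).
Consequently, passing tests demonstrate the structural mechanisms (floors,
infeasible cells, power degradation), not the numeric V-scale power values
of the real instrument.

With the default tables (seed 1), 81 of the 110 grid cells are feasible;
the infeasible cells are young-age × high-impairment combinations of
late-developing subdomains, as with the real tables.

## Degenerate inputs and conventions

* Continuous GSVs are rounded to the *nearest tabulated* GSV, ties upward,
  and clipped to the table extremes (draws below the floor map to GSV 10).
* Ages are integer months; bands are half-open `[min, max)`; baseline ages
  are uniform on the integer months of the range; every participant ages
  exactly 6 months, and baseline and endpoint are scored in their own age
  bands. The synthetic age support extends one band past the oldest design
  range so endpoint ages remain scorable.
* Complete-floor classification defaults to "every member of an arm at the
  minimum at **both** timepoints"; `classify_floor(..., timepoints="endpoint")`
  relaxes this (the convention is not settled in the field).
* The ANCOVA on the GSV endpoint uses the continuous drawn values, not the
  table-rounded ones; rounding exists only on the V-scale path. The
  rounded values are retained in `TrialDataset`, so the discretized variant
  is one line away if wanted.

## Problem sizes

The acceptance script runs 5,000 replications per large-effect scenario and
10,000 per null scenario (~1.2M simulated trials in total), completing in
under a minute on one CPU thanks to the batched fitting. The test suite
uses 2,000–10,000 replications for calibration checks and 50,000 for the
closed-form power cross-check; property tests (hypothesis) cover table
validity over random generator configurations, mixture-variance bounds and
band-weight normalization.

## Known limitations

* Single follow-up, no dropout, fixed 12/12 allocation, no unequal or
  Bernoulli randomization; rate-of-change (longitudinal) analyses are out
  of scope.
* The generative model assumes normality of GSVs within an age range and
  takes the SEM-derived SD at face value; both are assumptions about, not
  measurements of, real impaired populations.
* V-scale power values depend on the synthetic tables and should be read as
  qualitative; only the GSV power, type-I calibration and design arithmetic
  are table-independent quantities.
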