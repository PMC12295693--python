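# Methods

This note documents the demographic model, the numerical choices, the
synthetic-data generator and the known limitations of the package, in the
order a user meets them.

## The age-stage, two-sex life table

The unit of observation is one individually reared insect followed by a
daily census from oviposition (age 0) to death.  Stages are fixed:
egg (1), six larval instars (2–7), prepupa (8), pupa (9), and the
mutually exclusive terminal stages female adult (10) and male adult (11).
The census convention: an individual is in stage *j* on day *x* if
entry(j) ≤ x < entry(next stage), and alive on day *x* if x < death day.
A stage's duration is the difference of consecutive entry days, so an
egg stage with entries {0, 3} lasts exactly 3 days.

All surfaces are raw census counts divided by the cohort size N:

- s(x,j) = (alive in stage j at age x)/N, l(x) = Σ_j s(x,j).
- f(x,j): eggs laid on day x divided by females alive on day x, nonzero
  only in the female-adult column; m(x) = Σ_j s·f / Σ_j s; the net
  maternity l(x)m(x) = (eggs laid on day x)/N, which makes
  N·Σ_x l(x)m(x) equal to the raw egg total *exactly* — this is asserted
  on every analysed cohort rather than treated as approximate.

Sex of individuals dying before adult emergence is recorded as
undetermined and never imputed; the two-sex bookkeeping only splits the
population at eclosion.  Censoring is supported in the data model (a
flag, mutually exclusive with a death day): censored individuals count in
s(x,j) until the censoring day and are excluded from duration means of
stages they did not complete and from longevity means.  The analyses
shipped here assume an uncensored cohort, which is how such rearing
studies are normally run.

### Population parameters

- R₀ = Σ l(x)m(x).  Identically F·N_f/N, where F is mean eggs over all
  female adults.  `net_reproductive_rate_two_sex` exposes the identity so
  R₀ can be recovered from published summary statistics.
- r solves Σ_x e^(−r(x+1)) l(x)m(x) = 1.  The (x+1) exponent with age
  indexed from 0 is the convention of the standard age-stage two-sex
  software; the (x) convention would shift r, so the choice is fixed and
  documented here.  The left side is strictly decreasing in r, so the
  root is unique whenever R₀ > 0; at R₀ = 0 the rate is reported as
  undefined (an error), never as a sentinel number.
- λ = e^r and T = ln R₀ / r.  T is taken from this identity (not from
  Σ x·l(x)m(x)/R₀) so that the reported R₀, r and T are mutually
  consistent, matching how the triplet is normally tabulated.

**Root finding.**  Bisection on [−1, 2] per day⁻¹ (expanded outward if
the residual does not change sign there) to 1e−12 on r, followed by one
guarded Newton step.  The residual at the returned root must be below
1e−10 or a numeric error is raised.  The solver is vectorised across
rows of a net-maternity matrix; the bootstrap uses the same code path as
the single-cohort case.

### Life expectancy and reproductive value

The survival grid also records the empirical one-day transition counts
T[x, j, y] (individuals in (x,j) at x and (x+1,y) a day later; the row
deficit is deaths).  Both grids are backward recursions over these
observed transitions:

    e(x,j) = 1 + Σ_y P(x,j→y) e(x+1,y)
    v(x,j) = f(x,j) + e^(−r) Σ_y P(x,j→y) v(x+1,y)

with P the transition fractions.  Two exact consequences serve as
self-checks on every cohort: e(0,1) equals the arithmetic mean lifespan
(the recursion telescopes to total person-days / N regardless of any
Markov assumption), and v(0,1) = λ whenever r solves the Euler–Lotka
equation for the same schedule.  Cells never occupied are reported as 0.

## Bootstrap inference

The sampling unit is the individual: B resamples of size n with
replacement (a multinomial count vector per resample).  Every statistic
handled — R₀, r, λ, T, mean longevity, F, F_r, s_a, the three
development rates, pupal weight — reduces to dot products of the count
vector with per-individual aggregates, so resampling is vectorised; a
unit test proves the vectorised path numerically identical to literally
rebuilding each resampled cohort and re-running the grid→parameter
pipeline.  Reported per statistic: the original-sample point estimate,
bootstrap mean, SE (sd of replicates), and percentile CI.

Resamples that contain no eggs have R₀ = 0 and are retained in the R₀
distribution — dropping them would bias R₀ upward — while r, λ and T are
undefined there and excluded, with the degenerate count reported.  At the
study's sex ratios and n = 100 such resamples essentially never occur.

**Paired test.**  Both cohorts are resampled in the same iteration; when
the cohorts have equal size a single count draw is shared between them,
so comparing a cohort against itself gives a degenerate difference of
exactly 0 and p = 1.  The p-value is the two-sided percentile convention
p = min(1, 2·min(P(d ≤ 0), P(d ≥ 0))).  The original software for this
analysis does not document its exact rule; this convention is therefore
a flagged package choice.  Its operating characteristics under the
generator's study-scale conditions are measured in the test suite: type-I
error at α = 0.05 over 500 null experiments falls in [0.03, 0.07], and
power against a 2-fold R₀ difference at n = 100 is ≈ 75–80% — a 2-fold
gap is only ~2.7 bootstrap SEs when R₀'s sampling CV is ~16%, as the
published SEs imply — so the regression guard in the tests is set at 60%,
well below the measured value but far above chance.

B defaults to 10,000 (desk scale, sub-second at n = 100); the
study-scale 100,000 is a flag away and changes runtime, not behaviour.
One root seed drives everything; identical configuration gives
bit-identical results.

## Assay statistics

Choice-assay rates are 100·count/total per replicate (all-zero replicates
are excluded with a warning).  Comparisons run one-way ANOVA on
asin(√p)-transformed proportions (transform applied to p in [0, 1], not
to percentages) followed by Duncan's multiple range test: ranked means,
span-p least significant ranges r_p·√(MSE/n_h) with r_p the
studentized-range quantile at Duncan's protection level 1−(1−α)^(p−1)
(scipy's `studentized_range`), harmonic-mean n for unbalanced groups, and
the containment rule (no difference inside a non-significant span is
declared significant).  ANOVA edge cases are explicit: identical groups
F = 0, zero within-group variance with unequal means F = +∞.

## Synthetic cohorts

The generator emulates the individually reared cohort the analyses
assume.  Integer quantities are `min_days` plus a count offset drawn
Poisson (default), negative-binomial (var = μ + μ²/k) when
overdispersion is wanted, or exactly round(μ) for degenerate stages —
this gives independent control of location and spread down to the
zero-variance egg stage.  Death strikes a stage with probability
1 − survival and falls uniformly inside the drawn stage duration.  Sex is
latent at pupation (so pupal weight, normal by sex, can differ between
sexes) and recorded at emergence.  A female's schedule is: adult
pre-oviposition period, a block of oviposition days over which her total
fecundity (drawn with configurable mean/dispersion, multiplied by a
zero-laying fraction that separates F from F_r) is split by a uniform
multinomial, then a post-reproductive survival tail.

The four presets (`sweet`, `waxy`, `common`, `silage`) encode the
published third-generation magnitudes: per-stage survival chains taken
as ratios of successive stage-completer counts, stage-duration means,
sex splits, F/F_r, APOP, oviposition days, adult longevities and pupal
weights.  They are calibration conveniences that reproduce the right
orders of magnitude (e.g. the sweet preset yields R₀ ≈ 179 with
bootstrap SE ≈ 29 against the published 178.70 ± 28.66); they are not
reconstructions of the unreleased raw records, and passing recovery
tests on them demonstrates correctness of the pipeline under realistic
magnitudes, not fidelity to the original animals.

What the generator does **not** model: correlations between an
individual's stage durations (all independent), day-to-day fecundity
shape within the laying block (uniform split), temperature or density
dependence, censoring, and any between-generation carry-over.  Real
cohorts likely violate the independence assumptions mildly; none of the
identities or estimators used here require them.

Closed-form expectations (`expected_params`) follow by construction:
E[R₀] = femaleFraction · Π(stage survivals) · (1 − zeroFraction) ·
E[total eggs]; s_a = Π survivals; durations = min + μ.  These are the
recovery oracles for end-to-end tests (empirical R₀ within Monte-Carlo
error at n = 1000; bootstrap 95% CIs covering the analytic R₀ in ≥ 90 of
100 study-scale runs).

## Problem sizes in the shipped tests

The test suite and acceptance script run at desk scale as the package's
own defaults: cohorts of n = 100 (n = 1000 for one law-of-large-numbers
check), B = 1,000–2,000 for repeated-experiment studies, B = 100,000
only for the single exhaustive-enumeration comparison, 500 null
experiments for the type-I calibration and 200 seeds for the
duration-calibration check.  The full suite completes in well under a
minute on one core.

## Known limitations

- Daily census only; no sub-daily resolution, no smoothing of grids.
- One generation per cohort file; no overlapping generations, no
  egg-batch records (fecundity is per-female per-day).
- No population projection, temperature/density dependence, or
  multiple-testing correction across parameters (none is standard for
  this table layout).
- The e(x,j)/v(x,j) recursions condition on the empirical daily
  transitions, which treats the cohort's stage dynamics as Markovian
  between census days; the two anchor identities above hold regardless,
  but interior cells of very small cohorts are noisy.
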