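# Methods

## Scientific setting

In low- and middle-income countries the population mean height-for-age
Z-score (HAZ) of children declines from birth through roughly 24 months.
Two mechanisms could produce that decline: faltering concentrated in a
high-risk subgroup, which must widen (and skew) the HAZ distribution as
the subgroup diverges from its peers, or a whole-population downward
shift, which moves the distribution without widening it. The two are
distinguishable from cross-sectional survey data by tracking the
*shape* of the HAZ distribution — SD, median, and the tail distances
Δp5 = mean − p5 and Δp95 = p95 − mean — as the mean falls with age.

This package implements that analysis chain over synthetic survey data,
plus a Monte Carlo simulator that makes the subgroup-versus-population
contrast quantitative.

## Survey-age units and weighted parameters

Children are grouped into 12 discrete 3-month age bands of exactly 91.3
days (≈ 365.25/4; sensitivity widths 30.44 and 182.6 days for 1- and
6-month bands). Bands are half-open `[k·w, (k+1)·w)`; with integer ages
in days and w = 91.3 a boundary tie is impossible. HAZ values outside
±9 are excluded as implausible (±6 in the stricter sensitivity setting);
exclusion counts are logged and reconciled (children in = excluded +
banded).

One survey × one band is a **survey-age unit**. Per unit we compute
survey-weighted mean, median, SD, p5, p95, Δp5 and Δp95.

*Weighted quantile definition.* Weights are treated as frequency
(replication) weights: with W = Σw, the q-quantile interpolates linearly
between the "expanded order statistics" at positions ⌊q(W−1)⌋ and
⌈q(W−1)⌉ on the cumulative-weight scale. For integer weights this equals
numpy's default (Hyndman–Fan type 7) percentile of the sample with each
value repeated wᵢ times — exactly, which is what the replication-oracle
tests pin down. A consequence worth knowing: multiplying all weights by
a constant c ≠ 1 changes percentiles by O(1/W) (mean and SD are exactly
scale-invariant); at survey sample sizes this is far below any
scientific resolution. Weighted SD uses the population divisor Σw; a
frequency-weight (Σw − 1) correction is available as a config switch
(`BandingConfig.sd_ddof1`) and is negligible at survey n.

Units with fewer than `min_children_per_unit` children (default 1, i.e.
no exclusion — a fully populated 179-survey dataset yields exactly
179 × 12 = 2148 units) are dropped; sparse units mainly destabilise the
tail percentiles.

## Pooled age-band summaries

The pooled estimate of a parameter in a band is the unweighted mean over
the units in that band — units are deliberately not weighted by child
count, because the inference target is the survey level. The 95% CI uses
cluster-robust (CR1 sandwich) standard errors with country as the
cluster, the standard survey-analysis treatment of "accounting for
clustering by country"; a country-random-intercept alternative is
available behind a flag. The normal critical value is used with ≥ 30
country clusters, t with (J−1) df below that. Coverage of this CI under
exchangeable country effects is verified by simulation (500 replicates,
40 clusters) to sit within 3 points of nominal.

## Three-level mixed models

For each outcome (SD, median, Δp5, Δp95), units are modelled as

    y_ijk = β₀ + β₁ x_ijk + u_k + a_jk + b_jk x_ijk + ε_ijk

with x = −(unit mean HAZ), so β₁ > 0 means the outcome rises as the mean
falls; u_k is a country random intercept, a_jk and b_jk survey-level
random intercept and slope, estimation by REML (statsmodels MixedLM,
L-BFGS, 200 iterations max). The model leans on *within-survey*
variation of mean HAZ with age, which removes confounding by
between-survey differences in level.

Two implementation choices matter:

* **Independent survey intercept/slope.** MixedLM cannot profile a
  covariance between variance components nested below the top grouping
  level, so the survey random intercept and slope enter as independent
  components rather than an unstructured 2×2 block. This affects
  efficiency, not consistency, of the fixed effects; slope-CI coverage
  is verified at nominal level by simulation (95% ± 4 points over 300
  replicates at 100 surveys × 12 units, generated with zero covariance).
* **ICCs under a random-slope model** are ill-defined as a single
  number; we report intercept-level variance shares evaluated at x = 0:
  ICC_country = var_c / (var_c + var_s + var_e) and
  ICC_survey-in-country = (var_c + var_s) / (var_c + var_s + var_e).
  A config option refits a random-intercepts-only model for ICC
  reporting, and percentile CIs are available via parametric bootstrap
  (an implementation choice; simulate from the fitted components on the
  observed design and refit).

Fixed-effect CIs use the normal approximation (appropriate at thousands
of units and tens of countries). Stratified slopes come from one model
per stratifier with stratum main effects and stratum-by-x interactions,
sharing the random structure; strata with < 2 surveys are flagged and
excluded. Per-survey OLS slopes (the saturated fixed-effects interaction
model) feed forest plots; BLUP survey slopes are fixed slope + predicted
random deviation and are verified to have no larger spread than the OLS
slopes (shrinkage).

Non-convergence is flagged on the returned fit (with the optimizer
warnings attached), never silently ignored; a fit that raises internally
becomes a `ConvergenceError`.

## The synthetic survey generator

Because the real microdata are access-restricted, every estimation stage
is exercised on synthetic data whose truth is known. The generator
emulates: 64 countries × 179 surveys (25% of countries contribute one
survey, 20% two, the rest three or four — matching the compilation's
composition); per-survey child counts log-normal with median 3159 and
IQR 2495, clipped to [351, 27352]; ages uniform over [0, 1096) days (the
real within-survey age distribution is not documented; reported per-band
counts are consistent across bands); observed HAZ = m(age) + s(age)·Z +
e(age)·Z′ with configurable curves. Defaults: mean curve piecewise
linear −0.4 (birth) → −1.9 (24 mo) → −2.0 (36 mo); biological SD
constant 1.2; measurement-error SD declining linearly 0.8 → 0.2, the
age-differential error hypothesised to explain the wide distribution in
early infancy. Sampling weights are log-normal (dispersion 0.5,
normalised to mean 1 within survey) and independent of HAZ, so weighted
estimators are unbiased for the configured truth; a HAZ-correlated
weight mode exists purely for stress tests. Region/income/year labels
follow the compilation's categorical proportions.

What the generator does *not* emulate: cluster-level sampling designs
(weights are i.i.d., not informative), non-Gaussian HAZ shapes, digit
preference and other data-quality artefacts, and country-level
heterogeneity in the age trajectory beyond sampling noise. Passing tests
therefore validate the estimators and the pipeline logic, not any claim
about real surveys.

A separate unit-level generator (`generate_linear_units`) draws
survey-age units directly from the three-level linear model (defaults:
β₁ = −0.20, country/survey intercept SDs 0.1, slope SD 0.05, residual
SD 0.1, x spanning 0–2 like the real mean-HAZ decline) for
parameter-recovery studies where child-level sampling would only add
noise between the truth and the model.

## The faltering simulator

10,000 children start at N(0, 1). Exposure (fraction p ∈ {0.25, 0.5,
0.75, 1.0}) is assigned once at baseline and never changes. Each of 20
steps lowers the population mean by 0.1: exposed children decline by
Normal(d, 0.1·d) with d = 0.1/p (so 25% exposure forces a 0.4 mean
decline in the exposed). Normal is the minimal reading of "vary
randomly with SD a tenth of the mean decline"; a truncation-at-zero
switch (no negative declines) exists and is off by default. Each
scenario runs 1000 replications; reported trajectories are
per-replication sample statistics averaged over replications, with Monte
Carlo standard errors from the replication spread. Everything is
vectorised as a (replications × children) matrix; a full four-scenario
grid takes well under a minute on one CPU.

For random selection without a floor the population at step k is a
two-component Gaussian mixture, giving the closed-form oracle

    mean_k = −0.1k,
    var_k  = (1−p) + p·(1 + k(0.1d)² + (kd)²) − (0.1k)²,

which yields final-step SDs 3.607 / 2.237 / 1.528 / 1.001 for p = 0.25 /
0.5 / 0.75 / 1.0. The simulator is required to match the oracle within 3
Monte Carlo SEs at every step; the published averaged SDs (3.63, 2.25,
1.55, 1.02, read from smoothed trends) sit within 0.03 of the analytic
values and within the ±0.05 band used for acceptance.

Variants: *preferential selection* is deterministic rank selection of
the lowest (or highest) p·n baseline HAZ values — the extreme,
reproducible reading of "preferentially selected"; *floor* censors
children below HAZ −6 (removed from all later summaries; a clamp mode
exists, off by default); *deficit gradient* scales each child's mean
decline by (1 + γ(haz₀ᵢ − mean haz₀)) with γ = 0.3, renormalised so the
population mean still falls exactly 0.1 per step (the direction is
specified — larger deficits at higher baseline HAZ — but no functional
form; linear-in-baseline is the simplest). Trajectory shapes are
classified (widening / narrowing / transient narrowing / stable) using a
practical-equivalence threshold of max(3 MC SE, 0.02 SD): at 1000
replications the analytic ~0.001 SD creep from accumulated decline noise
under whole-population exposure is statistically detectable but not a
meaningful widening. Smoothing of the published trend lines is cosmetic
and not reproduced; raw per-step averages are reported, and the
final-decrement value (mean exactly −2) is the quantity checked.

## Pipeline, seeds and determinism

The pipeline derives per-stage integer seeds from a single global seed
via `SeedSequence([global_seed, stage_code, index])`; the generator
itself spawns independent child streams for structure, HAZ draws,
measurement error and weights. Identical config + seed reproduces every
CSV byte-for-byte. Stage outputs are CSV (inspectable, diffable); the
run manifest (JSON) records the config hash, seeds, row counts at every
stage and exclusion counts.

## Problem sizes used in the checks

The validation studies run at "desk scale", chosen to give tight Monte
Carlo error while keeping the whole suite fast: the simulator at the
full published settings (10,000 × 20 × 1000, seconds per scenario when
vectorised); slope recovery at 100 surveys × 12 units × 300 replicates;
pooled-CI coverage at 40 clusters × 8 units × 500 replicates; the
median-tracks-mean check at 100 surveys × 2400 children; structure
counts at 179 surveys × 600 children. The analysis drivers regenerate a
full-scale compilation (~6 × 10⁵ children) from scratch in seconds.

## Known limitations

* The survey intercept–slope covariance is fixed at zero (see above);
  with strongly correlated real intercepts and slopes the fixed-effect
  SEs would be mildly misestimated.
* ICCs are intercept-level conventions under a random-slope model, not
  unique variance decompositions.
* The weighted quantile's replication semantics are one of several
  defensible definitions; all agree asymptotically and the choice is
  pinned by tests.
* The generator's weights are non-informative by default, so weighted
  and unweighted estimates differ only by noise; informative-design
  bias is out of scope.
* The simulator is the abstract population experiment — no ages,
  births, deaths (beyond floor censoring) or covariates.
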