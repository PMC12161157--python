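# Methods

This note documents the statistical procedures implemented in `fgmq`, the
assumptions behind them, the synthetic-data generator that defines the
package's test conditions, and the numerical choices that matter.

## Setting

Household survey programs measure female genital mutilation (FGM) twice
over: women aged 15–49 answer for themselves (self-report) and mothers
answer for each living daughter under 15 (proxy report). Both modules
record FGM status and, for FGM-positive respondents, the age at which it
happened. The analysis target is *data quality*, not prevalence:
completeness of the age-at-FGM item and digit preference (age heaping) in
it, compared across the two reporting modes, and the consequence of
quality differences for median age-at-FGM estimates by birth cohort.

## Pooling by weight denormalization

Each survey ships weights normalized to mean 1 within the wave. To pool
waves, each survey *s* with eligible population `T_s` (women 15–49 plus
girls 0–14 in the survey year, supplied as a configuration input) is
rescaled:

    w_denorm_i = w_norm_i · T_s / Σ_{j∈s} w_norm_j .

This is post-stratified rescaling: within-survey relative weights are
untouched (so within-survey estimands are unchanged), per-survey weight
sums equal `T_s` exactly (checked to 1e-9 relative), and each wave's
influence in the pool is proportional to the population it represents.
The formula is invariant to rescaling any survey's normalized weights by
a positive constant. By default the two modules are rescaled jointly
against a combined total; `by_module=True` rescales each module against
its own total where totals are supplied per module. Which convention a
given published analysis used is generally not stated; joint rescaling is
the default and both are exposed.

## Exclusion and infancy redistribution

Records whose reported age at FGM exceeds the respondent's current age are
internally inconsistent and are dropped (equality is retained); the
exclusion is a pure, idempotent filter with a per-survey audit. The
pipeline order is fixed as exclude → redistribute.

Women frequently answer "during infancy" instead of an exact age. These
answers are retained: "infancy" is interpreted as ages 0–5 inclusive
(configurable upper bound, `max_age=5` by default — a genuine assumption,
since respondents' own reading of "infancy" is unobservable), and each
approximate answer is redistributed according to the *anchor
distribution*: the weighted distribution of precise answers at ages 0–5
among women of the same survey. A survey with approximate answers but no
precise young-age answers falls back to the pooled all-survey anchor with
a warning. Two modes:

* **fractional** (default): the record becomes one copy per anchor age
  with weights multiplied by the anchor probabilities. Deterministic, no
  Monte-Carlo error; downstream weighted statistics are exact in the
  anchor. Zero-probability copies are dropped so weights stay positive.
* **stochastic**: a single age is drawn per record from the anchor
  (seeded). Keeps one row per respondent for record-level uses; agrees
  with fractional mode in expectation.

Both modes conserve the weighted FGM-positive mass exactly, and no
approximate sentinel survives redistribution. Wholly missing ages are
*not* imputed — missingness is itself an outcome under study.

## Completeness

Among FGM-positive respondents, completeness is the share whose age at
FGM is reported; an approximate infancy answer counts as reported. The
profile is computed as a weighted share by current age × module (also by
survey × module), with groups holding no FGM-positive mass flagged rather
than silently dropped. The self-/proxy-report contrast appears as a
discontinuity between ages 14 and 15 — the seam between the two modules.

## Age heaping: smooth-transition index

Classical digit-preference indices (Whipple, Myers) are undefined below
age 10, where most FGM occurs in the populations of interest. Heaping at
a target age *a* ∈ {5, 10, 15} is therefore measured as

    ratio(a) = C(a) / [ (C(a−1) + C(a+1)) / 2 ],

with `C(x)` the weighted FGM count at age *x*. The denominator is the
count expected if the age distribution were locally linear across
{a−1, a, a+1} ("smooth transition"); the ratio is exactly 1 under local
linearity, invariant to global weight rescaling, and strictly increasing
in any displacement of adjacent-age mass onto the target. The daughters'
module never reports age 15 (its respondents are under 15); a target of 0
is rejected since no lower adjacent age exists; zero expected mass with
positive observed mass yields +inf with a flag. Weighted counts are the
default, matching the pooled estimand; an unweighted switch exists.
Stratified heaping (by education, DoB completeness, cohort, survey) uses
the same grouping mechanism.

## Design-based logistic regression

The completeness model is fit on FGM-positive records only (the outcome —
age reported vs missing — is undefined otherwise), with treatment coding
referenced to: no education, earliest survey wave, daughters' module,
imputed date of birth; current age enters as one continuous term. Rows
with unusable education ("missing"/"other") are removed listwise and
counted. Factor levels that vanish after subsetting are dropped with a
warning.

Point estimates solve the weighted logistic score equations by IRLS
(Newton steps on the weighted information), converging when the largest
score component is below 1e-8 or the relative deviance change is below
1e-10, capped at 50 iterations; non-convergence raises an error carrying
the last iterate, and |estimate| > 15 triggers a separation warning.

The variance is Taylor linearization honoring the stratified cluster
design: per-observation scores `s_i = w_i x_i (y_i − p_i)` are summed to
PSU totals `z_hc`, centered within their stratum, and combined as

    V = B⁻¹ [ Σ_h n_h/(n_h−1) Σ_c (z_hc − z̄_h)(z_hc − z̄_h)ᵀ ] B⁻¹ ,

with `B = XᵀWX` at the solution. Wald intervals use Student's *t* with
design degrees of freedom #PSUs − #strata — the convention of standard
complex-survey software. A stratum reduced to a single PSU contributes no
variance (certainty treatment) and warns. Pooled denormalized weights are
the default analysis weights, switchable to per-survey normalized weights
or none. With every observation its own PSU in one stratum, the formula
reduces to the familiar heteroscedasticity-robust sandwich (up to the
n/(n−1) centering factor), which is how it is cross-checked in the tests
against an independently optimized fit. Multilevel models, finite
population corrections and replication-weight variance are out of scope.

## Medians and composition tables

The weighted median is the *lower* median on integer ages: the smallest
value whose cumulative weight reaches half the total. With equal weights
it equals the ordinary lower median; ties therefore resolve downward,
matching the integer granularity of reported ages. Medians are computed
per birth cohort for each module and both pooled (weighted by default);
a cohort with no FGM-positive mass in a scope yields NA. Composition
tables (per-wave FGM frequency, education/DoB composition, cohort counts,
age-at-FGM bands <1 / 1–5 / 6–10 / 11–15 / >15 / missing, where "<1"
means completed age 0) use unweighted counts and integer percentages
rounded half away from zero.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions
under which the pipeline's statistical guarantees are verified.

**Design.** Each survey wave draws a stratified two-stage sample: PSUs
within strata (notional PSU pools grow across strata, so inclusion
probabilities — and hence weights — differ by stratum, giving a real
design effect), a fixed number of respondents per PSU, weights = inverse
inclusion probability normalized to mean 1 per survey. Respondents are
women (15–49) or daughters (0–14) per the wave's module mix; daughters'
"mother's education" is drawn from the same education distribution, the
conceptual mother link being the shared cluster. Birth cohorts derive
from survey year minus age (oldest observed birth year 1960, a small
share with unusable cohort), FGM status is Bernoulli with cohort-specific
prevalence, and the true age at FGM is drawn from a configurable
distribution over ages 0–17, truncated at the respondent's current age.

**Reporting layer**, applied in order heap → infancy-code → missingness:
ages snap to the nearest multiple of 5 (window ±2 years, target within
0–17 and not beyond current age) with probability `heap_prob`; reported
ages ≤ 5 become the approximate infancy answer with probability
`infancy_prob`; the age is dropped per a logistic model on the log-odds
of *complete* reporting (intercept + women's-module effect + optional
age/education effects). Heaping and infancy coding default to the
women's module only — the proxy reports being cleaner is the modeled
contrast — while the missingness model spans both modules so the module
effect is a recoverable parameter. The closed displacement form for the
post-heaping smooth-transition ratio is implemented
(`expected_heaping_ratio`) and inverted (`solve_heap_prob`) so presets
can state a target ratio rather than a raw probability.

**Preset.** `preset_paper_like()` fixes the package's study conditions: a
ten-wave series (one women-only and one daughters-only wave, the rest
mixed) with per-wave sizes and module mixes proportional to a real
national series, eligible populations growing from 5.4M to 8.6M,
education 62% none / 20% primary / 16% secondary, 64% imputed dates of
birth, cohort prevalences from 36% (1960s) down to 16% (post-2020)
(yielding ≈34% women's and ≈22% daughters' module prevalence), an
early-childhood age distribution with lower median 3, completeness
intercept logit(0.99) with module effect log(0.16) (so ≈1% of daughters'
and ≈6% of women's ages are missing), 45% infancy coding, and a heap
probability solved at build time for a closed-form age-5 ratio of 2.5
(≈0.22 under the preset distribution). `scale` shrinks PSU occupancy for
quick runs without changing the design.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: household/fertility structure and true
mother–daughter linkage, geographic clustering of FGM prevalence,
non-response correlated with outcomes, interviewer effects, within-PSU
outcome correlation beyond covariates (so design CIs are exact rather
than conservative here), and any secular trend in the true age at FGM.
Tests demonstrate that the estimators recover known parameters under a
faithful design, not that any particular real series is well-calibrated.

## Numerical choices and problem sizes

Weights round-trip through CSV at 12 significant digits. Anchor
distributions must sum to 1 within 1e-12; conservation checks use 1e-9
relative tolerance. IRLS tolerances are as above. Monte-Carlo checks use
fixed seeds and 3-standard-error bands with a Poisson approximation for
count ratios. The test suite's simulation sizes are chosen for sharp
verification at interactive cost: 50 000 draws for heaping calibration
(null and ratio-2.5 recovery), 100 000 sentinel records for the
fractional-vs-stochastic agreement (total variation < 0.02), and 500
replicates of a 20 000-respondent survey for CI coverage of the module
effect (band 92–98%). The acceptance script runs the preset at scale 0.6
(~114 000 respondents).

## Known limitations

* The smooth-transition expected count is undefined at age 0 and noisy
  where adjacent-age counts are sparse (e.g. women's ages > 15).
* Fractional redistribution produces non-integer row multiplicities;
  unweighted composition tables should be built from raw or
  stochastically-redistributed records.
* Single-PSU strata are handled by the certainty convention rather than
  centering at the grand mean; with many such strata the variance is
  understated.
* The ingestion boundary is the harmonized CSV schema; native survey
  recode formats are out of scope.
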