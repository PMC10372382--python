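# Methods

## Data model

An invitee table has one row per invited individual: an opaque unique id,
an ordinal wave label (`wave_0` for participation after the initial
invitation, `wave_k` after the k-th reminder, `nonparticipant` as the
terminal state) and typed characteristic columns — binary (0/1),
categorical (declared levels) or continuous. Non-participants carry a
distinct sentinel label rather than a numeric wave index so they can never
slip into participant-only arithmetic. Variables flagged
`participant_only` (measurements taken at the screening itself, such as
blood pressure or a stool-test result) must be missing for every
non-participant; validation enforces this.

Missing values are a single empty token in files. For categorical
variables declared `missing_as_level`, missingness is recoded to an
explicit `Missing` level and counted like any other level; otherwise a
variable's mean uses complete cases within that variable (numerator and
denominator both drop the missing rows), while wave shares always use
full invitee counts. How invitees with partially missing register values
should be handled is genuinely underdetermined in this setting; the
complete-case-within-variable rule is this package's choice and is
visible in the per-cell `n` of every output.

Exclusion rules (`column == value` flags) apply in declared order; a row
removed by an earlier rule is not re-counted by a later one, so the audit
reproduces the sequential accounting style of cohort-construction
flowcharts, and applying the same rules twice removes nothing the second
time.

## Group summaries

Group means and proportions carry Wald 95% intervals: se = sqrt(p(1−p)/n)
for proportions, sample SD (denominator n−1) over sqrt(n) for continuous
variables, both with the exact normal 0.975 quantile (1.959964…, not
1.96). Continuous intervals use the normal rather than the t quantile;
at the group sizes this package targets (hundreds to tens of thousands)
the difference is far below reporting precision, and one uniform
normal-approximation rule keeps pooled/wave identities exact. Proportion
intervals are plain Wald — no continuity correction, no clipping — because
clipping would break the exact identity that the pooled-participant
estimate equals the wave-share-weighted average of wave estimates (which
is also the last cumulative point of the extrapolation model). Degenerate
cells (se = 0) and interval bounds escaping [0, 1] are flagged, never
altered.

## Estimators

*Substitution* computes ȳ_pop = Σ_k w_k ȳ_k + w_n ȳ_n with the population
shares taken from the full invitee counts and ȳ_n set to the last
participant wave's value (a caller may supply any stand-in, including the
observed non-participant value, which recovers the exact population mean).
An empty declared wave is an error: the wave value is undefined.

*Extrapolation* builds cumulative points (x̄_k, ȳ_k): x̄_k counts all
invitees through wave k over the invited total, ȳ_k averages the
non-missing values among those participants. The line is fitted by
unweighted OLS (numpy's least squares; the bootstrap engine uses the
closed-form normal equations, and the two routes are tested against each
other) and evaluated at x̄ = 1. Cumulative sample sizes ride along on the
points for diagnostics only — the fit is unweighted, with no covariates.
Predictions outside [0, 1] for proportions are reported unclipped with an
`out_of_range` flag.

The choice of *cumulative* points (waves 0..k pooled) rather than
per-wave points follows the model's geometry: each point answers "what is
the participant mean if recruitment had stopped after wave k", and the
prediction target x̄ = 1 is the cohort where recruitment never stops.

## Bootstrap

Uncertainty for all three estimators comes from nonparametrically
resampling invited individuals with replacement — unstratified by
default, so wave shares are re-estimated in every replicate and share
uncertainty propagates; within-wave stratified resampling is available
as an option. The default interval is normal-based: point estimate on the
original data ± z·SD of the B replicate estimates; percentile intervals
are available and labelled non-default. B defaults to 1000. Replicates in
which an estimator is undefined (a resample emptied a wave) are dropped
and counted; more than half failing is an error. A fixed-share
delta-method Wald interval for substitution is provided as a cheap
approximate alternative (`ci="wald"`); it ignores share estimation error.

All resampling is vectorised: per replicate the engine needs only wave
counts, per-wave non-missing counts and per-wave value sums, computed by
bincount over blocks of index draws (at most ~4M draws per block to bound
memory). Every variable and method shares the same resamples within a
call, so a multi-variable bootstrap is one coherent re-run of the whole
procedure per replicate. Results are deterministic given (table, B, seed).

## Synthetic cohorts

The generator emulates the structure of large invitation-based screening
cohorts: tens of thousands of invitees, two or three participant waves
with shares like 39/7/3/51 or 38/10/52 percent, register-style
characteristics whose wave-group means follow (or deliberately violate) a
monotone gradient, and participant-only screening outcomes.

Each individual draws a latent propensity U (uniform by default; a
beta(a, b) option exists — note the propensity distribution affects
variable means through the link functions, not just wave assignment).
Waves are assigned by *exact sample quantiles*: rank the cohort by U and
cut at the integer counts obtained by cumulative rounding of the target
shares, highest U first. This makes wave membership a deterministic
function of U, reproduces target counts exactly (the study-like presets
store shares as exact count ratios, so the default sizes regenerate the
published group sizes integer-exactly), and makes the continuum
assumption literal: waves are contiguous propensity strata.

Characteristic links (conditional mean given U): flat; linear
(base + g·(U−½)); logistic for binaries (log-odds linear in U, gradient
on the log-odds scale); a U-shaped quadratic (base + g·((U−½)²−1/12),
mean-preserving under uniform U) for continuum violations; and a monotone
step (base + g·1{U ≥ t}). Variables are conditionally independent given
U — real registers show joint dependence (income × education, say), so
simulation results speak to marginal distributions only, and passing
tests do not certify behaviour under realistic cross-characteristic
correlation. Continuous noise is homoscedastic normal, a deliberate
idealization of skewed quantities like a comorbidity index.

Ground truth is recorded from the full cohort before participant-only
masking; `analytic_truth` gives the sample-free expectation (closed form
under uniform U for all links except logistic, which uses quadrature).

Preset notes:

- `strokestop_like`, `screesco_fit_like`, `screesco_col_like`: gradients
  chosen so the expected wave-group means span the ranges observed in the
  corresponding published cohorts (e.g. immigrant 0.16 → 0.27; comorbidity
  0.55 → 0.82; the colonoscopy arm's male share uses the U-shaped link to
  reproduce its non-monotone early/late/never pattern).
- `linear_in_cumshare`: linear-in-U links under uniform U make the
  expected cumulative mean *exactly* linear in cumulative share (the mean
  of the top m order statistics of a uniform sample is linear in m), so
  extrapolation is correctly specified and unbiased at any cohort size.
- `substitution_exact`: a monotone step placed at the early/late
  boundary, so every reminder wave and the non-participants share one
  conditional mean and the last wave is a perfect stand-in. The step is
  deliberately kept away from the stand-in wave's own stratum edges:
  rank-based assignment shuffles individuals across stratum boundaries by
  O(n^−1/2), and a discontinuity at those edges would leak a
  finite-sample bias into the identity.
- `non_monotone`: equal thirds with expected wave means 0.5 / 0.2 / 0.5 —
  both estimators are provably biased (substitution expects 0.3,
  extrapolation 0.2, truth 0.4), quantifying what happens when the
  continuum fails.
- `flat`: no gradient; all three estimators unbiased, used for CI
  calibration.

## Evaluation

`run_simulation` generates independent cohorts, applies all estimators
(optionally with bootstrap CIs) and aggregates bias, RMSE, coverage, mean
CI width and failure rate per variable × method, each with a Monte-Carlo
SE (binomial sqrt(c(1−c)/R) for coverage; delta method for RMSE). Truth
comes from `analytic_truth` where available, else from the pre-masking
mean of a one-million-invitee reference cohort. Per-replicate seeds are
spawned children of the run seed, so a shorter run is a prefix of a
longer one with the same seed.

"Improved representativity" has no standard quantitative criterion; this
package operationalizes it as absolute error against truth versus the
unadjusted participant baseline, with exact ties awarded to the baseline
so improvement claims are conservative.

## Problem sizes and numerical choices

Simulation defaults are sized for desk-scale reproduction: bias checks
use 200 replicates of 20,000-invitee cohorts without bootstrap;
CI-calibration runs use 500 replicates of 5,000-invitee cohorts at
B = 400, which completes in minutes on one CPU and gives a coverage MC SE
of about 0.01 at nominal 0.95. Statistical assertions in the test suite
are stated in Monte-Carlo SEs (typically 3), never as bit-exact
cross-implementation values. Seeds below 2^31 everywhere; ties in U are
broken by stable sort order.

## Known limitations

- The wave label is the only participation information used; calendar
  time between reminders is ignored.
- Conditional independence given U (above): no joint-dependence
  scenarios.
- The comorbidity-style score is generated as a numeric value directly;
  deriving it from diagnosis histories is out of scope.
- No weighting or covariate-adjusted extrapolation variants: the
  regression is deliberately the plain two-or-three-point OLS the model
  prescribes.
- Wald and normal-based bootstrap intervals can undercover for very rare
  traits or tiny waves; the calibration results shipped in the tests
  cover proportions near 0.3 and well-behaved continuous scores, not rare
  outcomes.
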