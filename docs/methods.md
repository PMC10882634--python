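# Methods

## The frequency model

The response is the per-substance geometric mean of rater-proposed PSUR
frequencies (years). Proposals are strictly positive and right-skewed,
and rater disagreement is closer to multiplicative than additive, so
the geometric mean `exp(mean(log p))` is the natural aggregate; it
always lies between the smallest and largest proposal.

The model is ordinary least squares of `log(1 + F)` on `log(1 + x_i)`
for five regressors: years since first authorisation, signal
procedures requiring regulatory action (trailing 3 years), safety
referral procedures, total adverse-event cases (trailing 3 years), and
pregnancy-exposure cases. The log1p transform handles the many exact
zeros in the count variables while still normalising skewness; on the
natural scale the model is the power law
`(1 + F) = exp(b0) · prod_i (1 + x_i)^{b_i}`.

Assumptions: linearity on the log1p–log1p scale, homoscedastic errors,
and negligible error in the aggregated response (with R raters of
log-scale noise sd `s`, the aggregate carries residual noise
`s / sqrt(R)`, which is folded into the error term). Standard errors
are classical OLS; confidence intervals are 95% t-intervals with
`n − k − 1` degrees of freedom; goodness of fit is the adjusted R².

### Diagnostics

Homoscedasticity is tested with the Breusch–Pagan auxiliary regression
of squared residuals on the design. The default is Koenker's
studentized variant (`LM = n·R²_aux`, robust to non-normal errors); the
classic variant (`ESS/2` on `e²/σ̂²`, exact under Gaussian errors) is
available. Both are referred to χ² with k degrees of freedom. Residuals
whose squares are exactly constant short-circuit to statistic 0,
p-value 1 rather than running a degenerate auxiliary fit. Under a
homoscedastic Gaussian null at n = 100 the studentized test's measured
size is ~0.05 (2,000-replicate calibration in the acceptance script).

### Back-transformation

Table-style natural-scale estimates are produced in two modes because
"back to the natural value" admits two readings:

* `exponentiated` — the power-law form: `exp(b0)` and the raw
  exponents `b_i`.
* `marginal_effect` (default) — years-per-unit derivatives
  `dF/dx_i = (1 + F̂) · b_i / (1 + x_i)` at a reference point
  (default: sample means of the regressors). This is the additive
  reading that makes statements like "one signal procedure shortens
  the cycle by ~5 months" well-defined. CI limits map the coefficient
  CI endpoints through the same (monotone in `b_i`) formula; they are
  pointwise transforms, not delta-method intervals for the nonlinear
  functional.

### Prediction

Continuous predictions are `expm1` of the linear predictor. Cycles are
reported in whole years: round-half-up (the field reports only integer
cycles and states no rule; half-up is the least surprising), then
clamped to `[5, 13]` — 5 because a substance coming off a long deferral
is not returned to closer-than-5-year monitoring by this pathway, 13
because that is the historical deferral cycle. The `clamped` flag marks
predictions the clamp actually changed.

`cases_for_equivalent_reduction(effect, months)` converts a per-case
effect in years/case into the number of cases matching a reduction
given in months: `round(months / (12 · effect))`; e.g. at 0.02
years/case, a 5-month reduction ≈ 21 cases.

## Screening

Pearson correlations of candidate variables with the aggregate are
computed on raw (untransformed) values — the transform belongs to the
model stage. Zero-variance variables are flagged degenerate rather
than propagating NaN. Collinearity pruning examines every unordered
pair of candidates: at pair r² ≥ 0.80 (the smallest round threshold
covering the observed 0.82–0.93 subset-count correlations), the
variable earlier in an explicit preference list is retained. The
default preference keeps total cases over its fatal/life-threatening
and designated-medical-event subsets and keeps pregnancy over
paediatric cases, matching the fitted model's regressor set; the
preference is an argument because the source material is ambiguous
about the pregnancy/paediatric choice, and a user can flip it.

No p-values or multiplicity control are attached to screening
correlations; the screen is descriptive.

## Workload and allocation

An entry with cycle `f` and next DLP year `d` contributes submissions
at `d, d+f, d+2f, …` with `f` rounded to whole years (minimum 1) for
stepping; sub-year cycles contribute `ceil(1/f)` submissions in every
year from `d` on, because workload is tallied per calendar year.
Horizons are closed year ranges, default 2022–2100. The baseline
median is taken over 2022–2032 (even windows average the middle pair).

Scenario 2 extends every non-deferred cycle strictly between 1 and
5 years to 5 years; cycles of a year or less are exempt (close
monitoring of newly authorised products) and deferred entries are
untouched. Over a long horizon this cannot increase total submissions.

Two allocation policies:

* `from_start` — an entry with cycle `c` gets first DLP
  `start_year + c` (cycle 9 from 2022 → first review 2031; the
  5-year minimum → earliest 2027), recurrences every `c`.
* `capacity` — years are walked in order; while the year's running
  load (background + recurrences of earlier allocations) is below the
  cap, the next entry is allocated to that year and its future
  recurrences join the running load immediately. Default order:
  ascending cycle, ties by id — shorter predicted cycles proxy higher
  safety priority. Exhausting the horizon with entries left yields an
  explicit "incomplete" schedule listing them, not an exception.

Only the allocation pass is capped. Recurrences booked in earlier
years are never rescheduled, so post-allocation totals can exceed the
cap — deliberately, to reproduce the cumulative-recurrence overshoot a
fixed-cap policy exhibits in practice. Percent increase of a cap over
the baseline median is `round(100·(cap − median)/median)`; note that a
955/868 target is a 10% increase by this arithmetic, although it is
sometimes quoted as "approximately 7.5%" — the package reports the
arithmetic value.

List churn (new substances, removals, merges) is ignored: registries
are static, on the standing assumption that yearly turnover does not
materially move the totals.

## The synthetic generator

`GeneratorConfig` defaults define the emulated study conditions:
45 surveyed substances, 24 raters, a ~3,085-entry registry with 36.7%
deferred on a 13-year cycle with a 2025 DLP, 5.6% of deferred entries
unmapped, and a cycle mix giving a background median in the high
800s/year with ~37% of non-deferred entries on 2–4-year cycles (the
group a cycle-extension scenario touches).

* **Counts** are negative binomial (right-skewed, overdispersed);
  means and dispersions are config-exposed since no distributional
  facts beyond right-skewness are available.
* **Planted collinearity**: subset counts (fatal/life-threatening,
  DME, paediatric) are beta-binomial thinnings of their source count.
  Given the realised source moments, the Beta variance of the
  per-observation thinning probability is solved so the pair's
  population r² equals the target (0.93 / 0.82 / 0.89 by default).
  Thinning makes the subset invariant (`subset ≤ source`) structural
  rather than enforced by clamping, which would distort the planted
  correlation. Targets above the thinning maximum raise a
  configuration error.
* **True frequencies** come from the log1p model with configured
  coefficients (age-dominant positive, counts negative, matching the
  expected effect directions) and Gaussian log1p-scale noise
  (sd 0.15); rater proposals multiply the truth by lognormal noise
  (sd 0.20), floored at 0.25 years, so geometric-mean aggregation is
  the exactly-matched estimator.
* **Determinism**: every generator is a pure function of
  (config, seed), using independent child streams per generator.

What the generator does *not* emulate: the joint covariate
distribution of the real registry (so the realized distribution of
predicted cycles — e.g. the share in the 9–10-year band — is not
comparable to the real exercise), individual case reports, name/salt
granularity mapping, or list churn. Passing tests therefore establish
correctness of the algorithms and calibration of the statistics under
the stated generative assumptions, not agreement with the undeposited
registry.

## Numerical choices and problem sizes

* Rounding of predicted cycles and of the percent-increase report:
  half-up (`floor(x + 0.5)`).
* Geometric means computed as `exp(mean(log p))` in float64; survey
  proposals must be strictly positive, enforced at validation.
* Rank-deficient designs and undersized samples raise errors naming
  the aliased columns / the dimension, rather than silently pseudo-
  inverting.
* Capacity allocation is O(entries × horizon); the brute-force
  reference simulator used in tests re-derives every year's load from
  scratch (O(entries² × horizon)) and must agree exactly.
* Test and acceptance problem sizes: CI coverage uses 200 replicates
  at n = 500; Breusch–Pagan size uses 2,000 replicates at n = 100 and
  power 500 replicates at n = 200; planted-r² checks use n = 2,000–
  5,000; allocation oracles use ≤ 20 entries over ≤ 15-year horizons
  (120 random instances) plus a 400-entry cap grid. These sizes give
  Monte-Carlo error comfortably below the asserted tolerances.

## Known limitations

* CIs for marginal effects are transformed coefficient intervals, not
  delta-method intervals; they are exact only conditional on the
  reference point and the fitted `F̂`.
* The capacity policy is greedy; no smoothing or optimisation is
  attempted, and completion years are sensitive to the allocation
  ordering for caps near the background level.
* The pregnancy-versus-paediatric retention choice is genuinely
  ambiguous in the source material; the default follows the fitted
  model's regressor set and is configurable.
* `years_in_eurd` is taken as input; the package does not resolve
  authorisation dates (a helper converts a year pair to an age).
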