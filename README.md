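# eurdtool

Predicting Periodic Safety Update Report (PSUR) submission frequencies
for active substances, and simulating the review workload of allocating
them — a Python implementation of the EURD-tool pipeline for
pharmacovigilance planners and biostatisticians working with
EURD-list-like registries.

## The problem

EU-authorised active substances each carry a PSUR submission cycle and
a data lock point (DLP) on the EURD list. A large block of long-
authorised substances was parked on a 13-year cycle with a common DLP;
assigning each a risk-based cycle by individual expert assessment does
not scale, and allocating them all at once would swamp the assessment
network. The pipeline here addresses both halves:

1. **Prediction.** Expert raters propose frequencies for a training set
   of substances; proposals are aggregated by geometric mean (they are
   right-skewed) and regressed on readily available safety data. The
   model is ordinary least squares on the log1p scale,

   ```
   log(1 + F) = b0 + b1·log(1 + Years_EURD)
              + b2·log(1 + Signals_regulatory_action)
              + b3·log(1 + N_Safety_Referrals)
              + b4·log(1 + Cases)
              + b5·log(1 + Pregnancy) + e
   ```

   where `F` is the aggregated proposed frequency in years,
   `Years_EURD` the substance's age in the list, and the remaining
   regressors are trailing-3-year counts of signal procedures requiring
   regulatory action, safety referrals, total adverse-event cases, and
   pregnancy-exposure cases. Candidate variables are screened by
   Pearson correlation with the aggregate and pruned for collinearity
   (pairs with r² ≥ 0.80 keep one member). Predictions are
   back-transformed with expm1, rounded to whole years, and clamped to
   a 5–13-year operational window.

2. **Allocation.** Every registry entry generates recurring submissions
   (DLP year, then every cycle). Deferred substances are slotted in
   either all from a common start year (`from_start`) or greedily
   against a yearly capacity cap (`capacity`). The cap constrains only
   each year's allocation pass — recurrences of already-allocated
   entries are never moved, so later years can overshoot the cap (the
   cumulative-recurrence effect).

No real registry is distributable, so `eurdtool.synthetic` generates
seeded datasets with the structure the analysis assumes: negative-
binomial counts, planted pair correlations (r² = 0.93 / 0.82 / 0.89
between total cases and their subsets), lognormal rater noise, and an
EURD-like cycle/DLP mix.

## Worked example

```python
from eurdtool import (aggregate_survey, back_transform,
                      cases_for_equivalent_reduction, fit_log1p_model,
                      percent_increase, predict_cycle)
from eurdtool.synthetic import GeneratorConfig, generate_features, generate_survey

cfg = GeneratorConfig(n_substances=45, seed=7)
frame = generate_features(cfg)
survey = generate_survey(frame, cfg)
fit = fit_log1p_model(aggregate_survey(survey), frame)
print(f"adjusted R^2 = {fit.adjusted_r_squared:.3f}")
print(f"Breusch-Pagan p = {fit.bp_p_value:.3f}")
c = fit.coefficients_log_scale["years_in_eurd"]
print(f"years_in_eurd: {c.estimate:.3f} (95% CI {c.ci_low:.3f} to {c.ci_high:.3f})")
effects = back_transform(fit, "marginal_effect")
print(f"signal procedure effect: "
      f"{effects['signals_regulatory_action'][0]:.3f} years per procedure")
for p in predict_cycle(fit, frame.iloc[:3]):
    print(p.substance_id, f"{p.continuous_frequency_years:.2f}",
          p.rounded_cycle_years, p.clamped)
```

prints

```
adjusted R^2 = 0.785
Breusch-Pagan p = 0.325
years_in_eurd: 0.414 (95% CI 0.346 to 0.482)
signal procedure effect: -0.765 years per procedure
S0000 8.22 8 False
S0001 5.87 6 False
S0002 8.23 8 False
```

The fit explains ~79% of the variance in proposed frequencies on this
synthetic training set; the Breusch–Pagan p-value of 0.33 gives no
evidence against homoscedasticity. The log-scale age coefficient 0.41
means older substances get longer cycles; at the sample-mean reference
point, one signal procedure requiring regulatory action shortens the
predicted cycle by about 0.8 years. The three predictions show the
continuous estimate, the rounded integer cycle, and whether the
5–13-year clamp changed it.

Two planning identities, directly:

```python
cases_for_equivalent_reduction(0.02, 5.0)   # -> 21 cases match a 5-month cut
percent_increase(1000, 868)                 # -> a 1000/yr cap is +15% on an 868/yr median
```

## Command line

```
eurdtool synth --n 45 --n-registry 3085 --seed 1 --out-dir run/
eurdtool screen   --features run/features.csv --survey run/survey.csv \
                  --substances run/substances.csv --out-dir run/
eurdtool fit      --features run/features.csv --survey run/survey.csv \
                  --substances run/substances.csv --out-dir run/
eurdtool predict  --model run/model_fit.json --features run/features.csv \
                  --substances run/substances.csv --deferred-only --out-dir run/
eurdtool simulate --substances run/substances.csv --predictions run/predictions.csv \
                  --policy capacity --cap 1000 --out-dir run/
eurdtool report   --in-dir run/ --out-dir run/
```

Each stage writes a manifest with its configuration, seed, and input
file digests; identical seed and config give byte-identical outputs.

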