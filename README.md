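# frcompare

Comparative functional-response analysis for depletion feeding experiments.

Quantitative ecologists compare the predatory impact of consumers — for
example an invasive crab feeding on mussels under crossed temperature,
salinity and sex treatments — by fitting **functional responses**: the
per-capita feeding rate as a function of prey density. `frcompare` implements
the full analysis chain for experiments in which prey are *not replaced* as
they are eaten, exercised end-to-end on a bundled synthetic
foraging-experiment generator, so every stage is testable without external
data.

## The model

In a trial of duration *T* starting with *N₀* prey, the number killed *Nₑ*
under a Type II (saturating) response with prey depletion satisfies Rogers'
random predator equation

    Nₑ = N₀ (1 − exp(a (Nₑ h − T)))

where *a* is the attack rate and *h* the handling time. The implicit equation
has the closed-form solution

    Nₑ = N₀ − W(a h N₀ exp(−a (T − h N₀))) / (a h)

with *W* the principal Lambert W branch. Kill counts are modelled as
Binomial(N₀, Nₑ/N₀) and (a, h) estimated by maximum likelihood on the log
scale. Derived impact metrics follow the comparative-FR literature: the
maximum feeding rate 1/h and the functional response ratio FRR = a/h (higher
FRR ⇒ greater predicted ecological impact).

Around the core fit the package provides:

- **Response-type test** (`frtype`): sequential binomial logistic regressions
  of proportion killed on density — a significant negative first-order term
  indicates Type II, a significant positive first-order followed by a
  significant negative second-order term indicates Type III — plus the LOWESS
  visual diagnostic (span 0.9).
- **Bootstrap** (`bootstrap`): nonparametric resampling of trials (default
  n = 2000) giving percentile CIs for (a, h) and 95% confidence envelopes
  around the fitted curves for between-group comparison.
- **Consumption GLM** (`glm`): quasibinomial factorial GLM of proportion
  killed on sex × temperature × salinity × density with Type III
  analysis-of-deviance F-tests (sum-to-zero contrasts), backward stepwise
  elimination, and Wald contrasts of density slopes between temperatures
  within a sex.
- **Pipeline** (`pipeline`, CLI `frcompare`): control-mortality check with
  optional Abbott correction, then GLM → type tests → fits → bootstrap,
  exporting plot-ready CSV tables and a machine-readable summary.
- **Synthetic data** (`synthetic`): an event-driven foraging simulator
  (exponential search, fixed handling) and a binomial generator matched to the
  fitting likelihood, over a fully factorial design (default: densities
  1–64, 5 predator replicates per cell, 3 predator-free controls per abiotic
  cell — 416 units).

Estimators follow scikit-learn conventions (`fit`, fitted `*_` attributes,
`get_params`); `fit_rogers`, `type_test`, `bootstrap_fit`,
`fit_quasibinomial`, … are thin functional wrappers.

## Worked example

```python
import frcompare as fc

design = fc.default_design()          # 8 densities x 2 sexes x 2 T x 2 S, 416 units
scenario = fc.default_scenario()      # bundled group-level (a, h) parameters
trials = fc.simulate_experiment(design, scenario, generator="binomial", seed=1)

df = fc.trials_to_frame(trials)
group = df[(df.sex == "M") & (df.temperature == 22.0) & (df.salinity == 15.0)]

fit = fc.fit_rogers(group)
metrics = fc.impact_metrics(fit)
boot = fc.bootstrap_fit(group, n_boot=2000, seed=7)
tt = fc.type_test(group)
```

Output:

```
type call: TypeII  (first-order term -0.044, p = 2.02e-28)
attack rate a  = 2.644  95% CI [2.058, 3.511]
handling time h = 0.072  95% CI [0.061, 0.086]
max feeding rate 1/h = 13.85 prey per period
FRR a/h = 36.60
```

Read: this group's response is saturating (Type II — the proportion of prey
killed falls as density rises); the fitted attack rate and handling time (in
experimental-period units, here 1 period = 72 h) are close to the generating
values (3.134, 0.080); at saturation the predator handles about 14 prey per
period; and the FRR summarizes both into a single impact score for ranking
groups.

The same analysis, from the shell:

```sh
frcompare simulate --seed 1 --out trials.csv
frcompare analyze --input trials.csv --out results/
```

which writes `type_tests.csv`, `functional_response_fits.csv` (a, p-values,
h, 1/h, FRR per group), `bootstrap_envelopes.csv`, `lowess_curves.csv`,
`consumption_glm.csv` (per-term F, df, p, retained flag) and `summary.json`.

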