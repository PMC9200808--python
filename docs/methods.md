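# Methods

This note records the models, numerical choices and design decisions behind
`frcompare`, and what the bundled synthetic experiments do and do not
establish about real data.

## Data model and units

A trial is one experimental unit: treatment factors (sex; water temperature;
salinity), initial prey count `N0`, prey killed `Ne`, duration, and a control
flag for predator-free units. Durations are stored in **experimental-period
units** (1.0 = one feeding period; the bundled design records 72 h as the
period's wall-clock length, as metadata only). Attack rates are then
per-period clearance coefficients and handling times fractions of a period,
which puts the maximum feeding rate 1/h on the natural scale of prey per
period — the scale on which published comparative tables report it (e.g. a
handling time of 0.032 periods ⇒ ≈31 prey per period against a maximum
offered density of 64). Factor levels are parsed case-insensitively from CSV;
a configurable column map lets tables with arbitrary headers be ingested.

## Rogers random predator model

Without prey replacement the Type II response must account for depletion:
`Ne = N0 (1 − exp(a (Ne h − T)))`. We solve it in closed form via the
principal Lambert W branch, `Ne = N0 − W(a h N0 e^{−a(T − h N0)})/(a h)`.
The W argument is nonnegative, so the principal branch is real; for large
arguments (a h N0 ≫ 1) the argument overflows in double precision, and the
solver switches to solving `w + log w = log z` by Newton from the two-term
asymptotic expansion. Against an independent 1-D root-bracketing oracle the
closed form agrees to better than 1e−9 relative error over wide random
parameter ranges (the acceptance suite checks 1,000 draws). Limits: `h = 0`
reduces to exponential depletion `N0(1 − e^{−aT})`; `a = 0`, `T = 0` or
`N0 = 0` give 0. The solution is nondecreasing in `a`, `T`, `N0`,
nonincreasing in `h`, and bounded by `min(N0, T/h + 1)` (property-tested).

**Likelihood.** Kill counts are Binomial(`N0`, `Ne/N0`) with `Ne` from the
deterministic solution — the standard likelihood for non-replacement designs.
Kill probabilities are clamped to `[1e−9, 1 − 1e−9]` so total depletion
(every prey eaten) keeps the log-likelihood finite.

**Optimization.** Maximum likelihood on `(log a, log h)` (positivity by
parameterization): a Nelder–Mead simplex started from a disc-equation
linearization (regression of `T/Ne` on `1/N0`; slope `1/a`, intercept `h`;
fallback `(1, 1/max density)`), polished by BFGS with the **analytic
gradient** obtained by implicit differentiation of the Rogers equation:

    dNe/da = (N0 − Ne)(T − Ne h) / (1 + a h (N0 − Ne))
    dNe/dh = −a (N0 − Ne) Ne / (1 + a h (N0 − Ne))

Convergence tolerance 1e−8 on the NLL. Standard errors come from the inverse
numerical Hessian at the optimum on the log scale and are delta-method
transformed; Wald p-values for `a` and `h` are reported on the natural scale.
A fit from a single prey density is flagged ill-posed; all-zero kills raise a
no-information error (the attack rate is unidentifiable). Warm-started
bootstrap refits use a damped-Newton fast path (finite-difference Hessian of
the analytic gradient) that falls back to the full simplex route when it
stalls; on resampled datasets it reproduces the full route's estimates to
≈1e−9 relative.

**Impact metrics** `1/h` and `FRR = a/h` are computed from unrounded fitted
values, never from rounded table entries.

## Response-type classification

Two binomial logistic regressions of proportion killed on density are fit
sequentially: `logit p ~ N0` supplies the first-order term, `logit p ~ N0 +
N0²` the second-order term. Type II ⇔ significant negative first-order term;
Type III ⇔ significant positive first-order term and significant negative
second-order term; otherwise indeterminate (α = 0.05, Wald tests). Testing
the first-order term in the density-only model is deliberate: under strong
depletion the proportion killed is pinned near 1 across the low densities,
and in a joint quadratic fit the `N0²` term absorbs much of the decline —
measured at the bundled study's replication this costs the joint-model test
30–40 points of power for the fastest-feeding groups, while the sequential
test detects Type II essentially always (and stays conservative under
density-independent nulls, false-positive rate ≈0.7% at α = 5%). Perfect
separation (diverging coefficients, detected by enormous Wald SEs) yields an
indeterminate call with a flag rather than an error.

The LOWESS diagnostic is locally weighted linear regression with tricube
weights over the nearest span-fraction of points (default span 9/10, zero
robustifying iterations), evaluated at the observed densities and clipped to
[0, 1] for reporting; it is cross-checked in the tests against an independent
pure-Python implementation of the same smoother.

## Bootstrap

Nonparametric: trial rows are resampled with replacement (same n,
unstratified — the design does not imply strata once a group is fixed),
the model refit per replicate, and 2.5/97.5 percentile intervals taken for
the parameters and for the fitted curve on an integer density grid
(1..max observed). Default 2000 replicates. Failed refits (e.g. resamples
with no kills) are dropped and counted, not redrawn, keeping the
seed-to-output map deterministic; a warning is attached past 20% failures.
Percentile (not BCa or studentized) intervals are used; they are equivariant
to the log reparameterization used in fitting. Calibration, measured over 200
synthetic experiments at study-scale replication (40 trials per group), puts
the attack-rate interval's coverage at the low edge of the nominal band
(≈91–95%) — the familiar mild undercoverage of percentile intervals at small
n — which is why group comparisons should read envelope *divergence*
qualitatively rather than as exact 95% statements.

## Consumption GLM

Proportion killed is modelled by a binomial-logit GLM on the full sex ×
temperature × salinity × density factorial (density continuous and untransformed,
so every term costs one degree of freedom). Overdispersion is handled
quasibinomially: φ = Pearson χ²/df, leaving coefficients **identical** to the
binomial fit (asserted bitwise in the tests) and scaling all inference.
Factors are sum-to-zero coded — required for Type III tests to be marginal
means contrasts rather than baseline-level tests; this is enforced by the
default formula and documented loudly because silently refitting with
treatment contrasts would change every F below the highest-order term.

Type III analysis of deviance removes each term's columns from the full
design matrix (all other terms retained), refits, and refers
`F = (ΔDeviance/Δdf)/φ` to `F(Δdf, df_resid)`. Aliased terms (e.g. a constant
factor, which yields empty sum-contrast columns) raise an error naming the
term. Backward selection removes one term per step — the highest-p removable
term at p ≥ α, where removable means not contained in any retained
higher-order interaction — and refits until all removable terms are
significant; both the full-model and reduced-model deviance tables are
reported, since published tables often show the full model while the text
describes the reduced one. The post-hoc comparison of density slopes between
temperatures within a sex is an explicit Wald contrast: the difference of
design-matrix rows at densities d+1 and d (averaged over salinity levels)
gives the slope vector per cell, and the between-temperature difference is
tested with covariance scaled by φ and Student-t reference on the residual
df.

A note on the classical "Type I = Type III in balanced designs" equivalence:
it requires mutually orthogonal contrast columns and holds exactly only for
linear models. With an uncentered covariate interacting with factors the main
effects are not orthogonal to their own covariate interactions, and for a GLM
the deviance is quadratic only asymptotically. The property test therefore
checks the equivalence where its premises hold (factors-only balanced design,
equal prey counts ⇒ homogeneous IRLS weights) to a small tolerance; for the
full model, only the density-involving terms agree closely.

## Synthetic data generator

The generator exists so the whole chain can be validated against known truth.

- **Mechanistic**: a single predator alternates exponential search (rate
  `a·N_current`) and a *fixed* handling delay `h` (fixed, not exponential, so
  the continuum limit is the classical disc-equation derivation). Prey are
  identical, sessile, not replaced, and do not respond behaviourally. A prey
  counts as killed when its search ends within the trial, even if handling
  would run past the end. The deterministic Rogers solution is the mean-field
  limit of this process, **not** its exact stochastic mean: at trial-scale
  prey counts the simulated mean sits within a few percent of the closed form
  (exactly on it as h → 0, where the process is pure Markovian depletion) —
  the tests assert exact 3-SE agreement in the h = 0 limit and 5% relative
  agreement with handling.
- **Binomial**: kills ~ Binomial(N0, Ne_det/N0), matched exactly to the
  fitting likelihood; this is the generator used for calibration studies
  (recovery bias, bootstrap coverage, GLM test size).
- **Controls**: Binomial(N0, background mortality), default 0.005 per prey
  per period — a >99% control-survival regime in which the Abbott correction
  is checked but not triggered.
- **Default scenario**: eight (a, h) groups spanning the male ≫ female
  magnitude structure of the crab–mussel study the design emulates (male
  attack rates 1.3–3.1 and handling times 0.03–0.08 per period, female attack
  rates 0.56–0.84 with handling times 0.16–0.18; male handling lengthens with
  warming). Under these parameters the expected male/female consumption ratio
  over the full design is ≈2.6.
- **Reproducibility**: one seed per experiment; each row draws from a child
  RNG stream derived by counter, so rows are independent of iteration order.

What passing on synthetic data does *not* show: real feeding trials have
predator-individual heterogeneity, prey-size selection, and possible
within-trial nonstationarity (hunger decay) that neither generator emulates;
the binomial generator in particular understates overdispersion relative to
real data (φ ≈ 1 by construction). Conclusions about estimator bias and test
calibration transfer to real data only to the extent the binomial-depletion
model holds.

## Pipeline

Order: control-mortality check (pooled kills/prey per temperature × salinity
cell; Abbott-style correction of treatment kills — expected background kills
subtracted, floored at zero, rounded — applied only if any cell exceeds the
threshold, default 0.05, and *before* all downstream analyses) → consumption
GLM with Type III table and backward selection → per-group type tests →
per-group Rogers fits and impact metrics → bootstrap envelopes → CSV exports
and a JSON summary. Grouping defaults to the full sex × temperature ×
salinity cross. Runs are deterministic given (input, config, seed); per-group
bootstrap seeds derive from the config seed. The missing-controls case
proceeds uncorrected with a logged warning.

## Problem sizes used in validation

The acceptance suite runs at the bundled study scale (8 densities × 5
replicates per group; 416-unit experiments): 50 simulated experiments for
recovery bias at 1× and 10× replication, 200 experiments × 500 bootstrap
replicates for interval calibration, 200 mechanistic experiments for
type-test power, and 500 runs each for type-test and GLM null size. The
acceptance script uses a 500-replicate bootstrap per group; the library
default remains 2000.

## Known limitations

- No Type III (sigmoidal) or flexible-exponent model fitting; the fit is the
  Type II Rogers model only, with the type test guarding its use.
- No predator interference, prey switching, or alternative prey.
- No formal hypothesis test of between-group parameter differences; groups
  are compared by CI/envelope divergence, as is conventional.
- Percentile bootstrap intervals mildly undercover at small n (above).
- The quasibinomial dispersion is a single scalar; structured overdispersion
  (e.g. predator-level random effects) is out of scope.
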