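# Methods

## Model

The unit of analysis is the component patient group (study arm): `N` VAP
cases among `D` ventilated patients, incidence proportion `R = N/D`.
Analysis happens on the log-odds scale: `y = log(N/(D−N))` with
large-sample variance `v = 1/(D·R·(1−R))`. The random-effects model
assumes each group's true log-odds `θ_i ~ Normal(μ, τ²)` with observed
`y_i ~ Normal(θ_i, v_i)`; τ² captures genuine between-centre
heterogeneity (case mix, diagnostic practice), `v_i` sampling noise.
Groups — including multiple arms of one study — are treated as
independent; no within-study correlation is modelled.

The benchmark is the pooled μ of the observational groups together with
the 95% prediction interval `μ ± 1.96·√(SE² + τ²)`, the range in which
the true incidence of a new comparable group is expected to fall.
Component arms are profiled by comparing their raw point estimate
`100·N/D` against this band; values exactly on an endpoint count as
"within" (conservative for outlier claims).

## Estimators and numerical choices

* **τ² (pooling):** DerSimonian–Laird method of moments
  `max(0, (Q−df)/(S1−S2/S1))` by default, matching the standard
  behaviour of the era's pooling software; REML (bounded scalar profile
  maximization of the restricted likelihood, `xatol 1e-10`) as an option.
  τ² is estimated once and plugged into the weights; the pooled mean is
  not re-iterated.
* **Meta-regression:** design with an intercept encoding benchmark
  membership (reference), indicator columns for the non-benchmark series
  *present in the data* (a two-series subset would otherwise be
  singular), then optional covariates. Residual τ² by REML (default) or
  a method-of-moments extension `max(0, (RSS−(k−p))/tr(P))`; coefficients
  by GLS with covariance `(XᵀWX)⁻¹`; z-based CIs and p-values, no
  small-sample (Knapp–Hartung) adjustment by default.
* **Quantiles:** z (1.96 at 95%) throughout, never t — consistent with
  the interval arithmetic being reproduced.
* **Continuity correction:** `N → N+0.5`, `D → D+1` applied to both the
  logit and its variance when `N = 0` or `N = D`, flagged via
  `corrected`.
* **Trauma proportion** enters regressions as a fraction in [0, 1]: a
  one-unit coefficient is the 0% → 100% contrast.
* **Missing covariates** cause listwise exclusion with a logged count
  (`on_missing="drop"`); `on_missing="error"` rejects instead, naming the
  groups. No imputation.
* **Quality restriction** keeps majority-quality prevention arms while
  always retaining every benchmark group.
* **Quartiles** in descriptive tables use linear interpolation between
  order statistics (numpy's default, "type 7").
* **Singular designs** are rejected naming the collinear columns;
  REML non-convergence raises with the optimizer's diagnostics.
* **Caterpillar plots** sort by point estimate, ties broken by CI width
  ascending then label, on a logit-scaled axis with percentage ticks at
  {5, 10, 20, 30, 50, 70, 90}; SVG output is byte-deterministic (fixed
  hash salt, no date metadata).

## Synthetic evidence bases

`synthetic_data` generates arm-level data from the generative reading of
the model: `θ_i ~ Normal(logit(μ), τ²)`, `D_i` log-normal, `N_i ~
Binomial(D_i, invlogit(θ_i))`. Default stratum parameters are the
observed evidence-base geometry: benchmark k=45 (22.1%, τ²=0.34,
denominators median 264, IQR 83–567); non-antimicrobial control and
intervention k=35 each (20.4% / 17.1%, τ² 0.41 / 0.35, denominators 54,
29–92); SDD control k=33 and intervention k=34 (35.7% / 16.0%, τ² 0.63 /
0.59, denominators 57, 33–130). Covariate frequencies mirror the
observed study characteristics (e.g. 23/45 benchmark groups with
bronchoscopic diagnosis, 4 duplex SDD controls, majority-quality rates
16/35 and 4/33).

Two perturbations operationalize the competing explanations: a
**contextual shift** (additive log-odds on SDD control arms only) and a
**censoring rule** dropping low-incidence control arms after observation
(publication bias on reported results). Each stratum has its own child
seed stream (seed + CRC32 of the stratum name), so adding a stratum never
perturbs another's draws.

Choices where the source data constrain only partially:

* The **denominator model** is a two-parameter log-normal matched to the
  median and the IQR *ratio* (σ = log(q3/q1)/(2·z₀.₇₅)), floored at 10
  patients. The printed quartiles are asymmetric around the median
  (83–567 around 264), which a two-parameter family cannot reproduce
  exactly; the generator matches the median and the log-scale IQR width.
* **Trauma proportions** are Beta-distributed with mean set to the
  stratum's observed median and concentration 2 (broad, covering the
  reported 0–100% range).
* **Publication years** are uniform over the observed IQR.

What the generator does *not* emulate: within-study correlation between
arms, non-concurrent third arms, duplex pharmacology (duplex is an
annotation only, as in the regression models), secular trends, and any
dependence of covariates on incidence. Passing recovery tests therefore
show the estimators are correct under the assumed model, not that the
model captures every feature of the real evidence base.

## Calibration results and problem sizes

The calibration suite (run as ordinary tests) uses the benchmark
geometry: k=45, μ=22.1%, τ²=0.34.

* **Prediction-interval coverage** is checked over 10,000 simulated
  meta-analyses — a replicate count chosen so the Monte-Carlo standard
  error (~0.003) is small against the ±0.02 acceptance band — using REML
  τ². Measured coverage is ≈0.935. With the default DL τ² the plug-in
  interval covers ≈0.92 at this geometry: the DL estimate is noisy and
  biased low (mean ≈0.30 against a true 0.34) because the estimated
  sampling variances are correlated with the estimates; this is a known
  small-k property of plug-in prediction intervals, is why REML is
  offered, and is documented rather than corrected (the interval
  arithmetic itself is fixed at z=1.96).
* **Parameter recovery** (500 replicates): pooled mean within 0.5
  percentage points of truth and τ̂² within 0.05 — bands that combine
  Monte-Carlo error with the small systematic biases measured for these
  estimators (≈+0.3 pp on the mean from weight–estimate correlation,
  ≈−0.03 on DL τ²), and that are an order of magnitude below the effects
  under study (a 13.6 pp control-group gap; τ² contrasts ≥0.2).
* **Series-coefficient recovery** (500 replicates): a benchmark +
  SDD-control design generated at 22.1% vs 35.7% recovers the SDD
  indicator within 0.05 of `logit(0.357) − logit(0.221) = 0.67`.
* **Null profiling** (300 replicates of 45 benchmark + 33 exchangeable
  control groups): the fraction of control arms above the derived band
  stays within 2 points of the nominal 2.5% and the mean deficit within
  ±25 per evidence base. The excess over exactly 2.5% comes from the
  band being estimated and from classifying *observed* (sampling-noisy)
  incidences, as the profiling procedure does; a +0.77 contextual shift
  moves the above-band fraction past 10% and the deficit to ≈+250, so
  the diagnostic separates the hypotheses cleanly.

## Known limitations

* The logit/inverse-variance workflow carries a small transformation
  bias for proportion data (see above); a binomial GLMM would avoid it
  but would not reproduce the interval arithmetic this package exists to
  provide.
* The deficit estimator takes the 2.5% upper-tail assumption literally
  and is linear in the outlier count; it is a coarse order-of-magnitude
  diagnostic, not a bias-corrected estimate.
* Group-level (ecological) covariate adjustment cannot stand in for
  patient-level risk adjustment.
* The prediction band assumes exchangeability of new groups with the
  benchmark population; it is only as representative as the benchmark
  sample itself.
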