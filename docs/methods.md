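# Methods

## The estimation problem

Surveillance of small abdominal aortic aneurysms produces, per patient, a
handful of maximal-diameter measurements (cm) at irregular times over a few
years, with substantial measurement noise from the CT/ultrasound mix. The
package turns each series into a single growth rate (mm/yr) under five
different model families and quantifies how the choice of family changes
stability, temporal bias, forecasting accuracy and risk-factor inference.

## The offset-exponential growth model

The nonlinear models assume

    d(t) = exp(a (t + b)) + 2        [cm; t in years since first measurement]

The +2 cm offset encodes the assumption that, far enough in the past, the
aorta had its normal ~2 cm diameter; `a` (per year) controls how fast the
curve bends upward and `b` (years) translates it so the curve can meet any
detection diameter. Because an exponential has no single slope, exponential
fits are standardised to the *benchmark rate*: the linear rate between the
model-implied times at which the curve crosses 4.0 cm and 4.5 cm,

    t(d) = ln(d - 2)/a - b,   rate = 10 * 0.5 / (t(4.5) - t(4.0)) = 5a/ln(1.25)  [mm/yr].

The implementation computes the two crossing times and cross-checks the
closed form at every call. `a = 0` maps to rate 0 by convention (a flat
curve never crosses the benchmarks), consistent with the downstream rule
that negative rates are clipped to zero (raw values retained for audit).

## Estimators

* **first_last** — chord between first and last measurement. Predictions
  use the same chord.
* **linear_unpooled** — per-patient OLS of diameter on time.
* **exp_unpooled** — per-patient nonlinear least squares of the
  offset-exponential. Initialisation regresses ln(d − 2) on t over points
  with d > 2.05 cm; when fewer than two such points exist or the log-slope
  is non-positive (typically shrinking or flat series), or the optimiser
  fails or returns non-finite values, the patient falls back to the
  unpooled linear fit, flagged in the output.
* **linear_mixed / exp_mixed** — hierarchical Bayesian versions with
  per-patient parameters drawn from population distributions (partial
  pooling). In the exponential hierarchy, log a_i ~ Normal(μ_la, τ_la), so
  a_i > 0 structurally and every patient has a well-defined benchmark rate;
  b_i ~ Normal(μ_b, τ_b); the likelihood stays on the raw cm scale, so
  noisy diameters at or below 2 cm are unproblematic.

### Priors and sampler

Hyperpriors are weakly informative on clinically plausible scales:
μ_α, μ_β, μ_b ~ Normal(0, 10); μ_la ~ Normal(−2, 1.5) (a ≈ 0.02–0.5/yr);
τ_α, τ_β, τ_la, σ ~ Half-Normal(1) on the cm scale. τ_b uses
Half-Normal(10): b is in years and spreads over roughly ±20 years across
detection sizes, so a unit-scale prior would badly misspecify it. Random
effects are independent (no intercept–slope correlation).

Sampling is an in-package vectorised Metropolis-within-Gibbs scheme:

* linear model: the per-patient (α_i, β_i) conditional is an exact
  bivariate normal (conjugate), sampled in closed form across all patients
  at once; population means are conjugate Gaussian updates; scales use
  log-scale random-walk steps.
* exponential model: the per-patient block is a joint random walk — but in
  (log a_i, v_i) coordinates with v = a·b, i.e. d = exp(a t + v) + 2. In
  the natural (log a, b) coordinates the posterior concentrates on a narrow
  ridge (a and b trade off to match the diameter at entry), which freezes a
  random-walk sampler; v is the log-scale intercept and is nearly
  orthogonal to log a. The prior stays on b itself via the change of
  variables (Jacobian e^{−la}).

Proposal scales adapt toward standard acceptance targets during warm-up
only. Defaults: 4 chains, 1000 warm-up + 1000 kept draws, seeded; a fit of
a 500-patient cohort takes a few seconds. "Central tendency" is the
posterior median of the pooled post-warm-up draws (mean available via
`center="mean"`): medians are robust to the skew typical of nonlinear-model
posteriors. Convergence is flagged per patient as split-R̂ > 1.1 (arviz) on
either per-patient parameter; estimates are reported for all patients
regardless, with the flag carried through every downstream table. On
realistic noisy cohorts >99% of patients converge; on *noiseless* data the
random-effect scales sit on the τ → 0 boundary and split-R̂ becomes
hypersensitive even though point estimates are exact — a known limitation
of variance-ratio diagnostics in degenerate regimes.

## Preprocessing rules

* **Merging:** measurements of one patient less than 150 days apart are
  averaged. Clustering is greedy left-to-right and *chained*: a point joins
  the cluster when its gap to the previous cluster member is under the
  window, so runs of close points collapse even when the endpoints are far
  apart (the plain reading of "less than 150 days apart"). The merged point
  sits at the arithmetic mean time with the arithmetic mean diameter —
  symmetric and order-free within a cluster. The operation is idempotent
  and conserves the cluster-size-weighted diameter sum.
* **Censored datasets:** the stability experiment needs ≥3 measurements per
  patient; left-/right-censored copies drop each patient's first/last
  point. Times are *not* re-zeroed: all five models are
  translation-invariant in time (b absorbs translation), and a common
  origin keeps per-patient deltas directly comparable.
* **Forecast splits:** each patient's final measurement is the target; the
  target and any measurement within 2 years before it are censored, the
  remainder merged (censor first, then merge), and patients with fewer than
  two training points are dropped.
* Dates convert to years at 365.25 days/year.

## Experiments

* **Stability:** every model is refitted to the full, left- and
  right-censored datasets; deltas are censored-minus-full *clipped* rates
  (clipping is part of the downstream-analysis convention). Summaries
  include the fraction of |Δ| > 1 cm/yr, an asymmetry statistic
  mean(Δ_left) + mean(Δ_right) (0 for direction-symmetric error) and a
  Mann-Whitney comparison of Δ_left against −Δ_right. The mean-based
  asymmetry statistic is sensitive to the unpooled exponential model's rare
  extreme refits; the median deltas and the distributional test capture
  that model's (symmetric) behaviour better.
* **Forecasting:** five metrics per model — mean squared, median absolute,
  mean absolute and mean raw (signed) projection error at the held-out
  target, plus the mean over patients of the mean squared residual to the
  training points. Raw error = predicted − actual, so negative means
  underestimation.
* **Risk factors:** clipped rates screened against covariates with
  two-sided Mann-Whitney U tests (categorical; exact for small tie-free
  groups, tie-corrected normal approximation otherwise) or Spearman rank
  correlations (numeric), at p < 0.05 with p < 0.1 flagged as borderline,
  deliberately without multiple-comparison adjustment; the number of tests
  performed is reported alongside. Each covariate is also tested against
  diameter- and age-at-detection to expose detection-window confounding.
* **Baseline:** per-model median clipped rate and Spearman correlation of
  rate with detection diameter, plus a by-detection-size breakdown.

## The synthetic cohort generator

The generator emulates the statistical structure the estimators assume:
offset-exponential natural history with lognormal population growth shapes
(log a ~ Normal(−2.6, 0.55), i.e. median a ≈ 0.074/yr and a median
benchmark rate ≈ 1.7 mm/yr); detection at a diameter uniform in
[2.5, 5] cm (the ectatic threshold upward), which pins b = ln(d₀ − 2)/a;
2–6 visits with Normal(1.2, 0.5)-year gaps truncated below; homoscedastic
Gaussian measurement noise of 0.15 cm; and categorical risk factors acting
multiplicatively on a (defaults: diabetes, prevalence 0.25, effect ×0.5;
hypertension, prevalence 0.8, effect ×1.25). Age at detection is
Normal(72, 8) and inert; imaging modality is recorded as an inert tag.
(b_mean/b_sd are used only if the detection window is disabled.)

It deliberately does **not** model: rupture, surgical repair, death or
informative dropout; modality-specific bias or heteroscedastic noise;
covariate effects on detection timing or follow-up length. Passing tests
therefore demonstrate correct behaviour under the assumed natural history —
irregular sparse noisy series with known ground truth — not robustness to
informative observation processes in real registries.

## Numerical choices and edge cases

* Exponent arguments are clamped at 60 before `exp` so wild MCMC proposals
  and extrapolations reject gracefully instead of overflowing.
* Noisy simulated diameters are floored at 0.1 cm (diameters must be
  positive); with default noise this is never reached in practice.
* All-tied rate vectors in a Mann-Whitney test report p = 1 with a warning;
  empty covariate groups are skipped with a warning.
* Per-patient fit failures exclude that patient from that model's metrics
  only, with logged counts, keeping models comparable.
* Determinism: every stochastic component (generator, samplers) takes an
  explicit seed; chains use `SeedSequence.spawn`.

## Known limitations

* On realistic cohorts (0.15 cm noise, 3–5 visits) the per-patient
  exponential shape a is only weakly identified: an exact grid posterior
  under the true generative prior attains ~19% median absolute relative
  error, and the hierarchical sampler matches that Bayes floor. Per-patient
  a estimates should be read as partially pooled tendencies, not precise
  individual measurements; cohort-level contrasts (the experiments above)
  are the reliable outputs.
* The mean-based stability asymmetry statistic is dominated by outliers for
  the unstable unpooled exponential model (see above).
* Hierarchical fits assume Gaussian noise with a single σ across patients
  and modalities.
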