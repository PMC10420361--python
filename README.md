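# aagrowth

Estimators of abdominal aortic aneurysm (AAA) growth rate, and a framework
for deciding which estimator to trust.

AAAs are monitored with periodic imaging; each patient contributes a short,
irregular series of maximal aortic diameters (cm). Clinical studies have
summarised "growth rate" in many incompatible ways — the chord between a
patient's first and last measurement, per-patient linear regression,
exponential curves, hierarchical mixed models — and the choice materially
affects which risk factors appear significant and how well future diameters
are predicted. This package implements five such estimators side by side,
plus the evaluation experiments that expose their differences, driven by a
synthetic surveillance-cohort generator so everything is reproducible
without patient data. It is written for biostatisticians and clinical
researchers modelling longitudinal diameter data.

## Models

For patient *i* with diameters *d<sub>ij</sub>* (cm) at times
*t<sub>ij</sub>* (years since first measurement):

| name | model |
|---|---|
| `first_last` | rate = (d_last − d_first)/(t_last − t_first); interior points ignored |
| `linear_unpooled` | per-patient OLS: d = α + βt |
| `exp_unpooled` | per-patient nonlinear LS: d = e^{a(t+b)} + 2, linear fallback on failure |
| `linear_mixed` | hierarchical Bayesian: d_ij = α_i + β_i t_ij + ε, (α_i, β_i) partially pooled |
| `exp_mixed` | hierarchical Bayesian: d_ij = e^{a_i(t_ij+b_i)} + 2 + ε, log a_i and b_i partially pooled |

The offset-exponential form decays to the normal aortic diameter of 2 cm in
the distant past; *a* sets the growth shape and *b* translates the curve to
the patient's detection size. Exponential fits are standardised to a single
comparable number, the **benchmark rate**: the linear rate between the
model-implied 4.0 cm and 4.5 cm crossing times, which reduces to
5a/ln(1.25) mm/yr. Rates are reported in mm/yr; negative rates are clipped
to zero for downstream analyses (raw values are retained).

The hierarchical posteriors are sampled with an in-package vectorised
Metropolis-within-Gibbs sampler (conjugate Gibbs for the linear patient
block, a reparameterised random walk for the exponential one), with
split-R̂ convergence flags per patient.

## Worked example

```python
import aagrowth as ag

cohort = ag.generate_cohort(ag.default_paper_like_config(seed=0))
merged = [ag.merge_close_measurements(s) for s in cohort]   # <150-day merges
cohort2 = ag.filter_min_measurements(merged, 2)

model = ag.ExponentialMixedModel(chains=4, warmup=1000, draws=1000, seed=0)
model.fit(cohort2)
print(model.rates_.head(3))
print("median rate:", model.rates_["rate_clipped_mm_per_yr"].median())
```

```
  patient_id      model  rate_mm_per_yr  rate_clipped_mm_per_yr  fallback  converged
0       P000  exp_mixed        2.070922                2.070922     False       True
1       P001  exp_mixed        1.457649                1.457649     False       True
2       P002  exp_mixed        3.657866                3.657866     False       True
median rate: 1.7154269010898824
```

Each row is one patient's standardised growth rate in mm/yr (here ~1.7 mm/yr
at the median, a typical small-AAA pace) with its linear-fallback and
MCMC-convergence flags. The evaluation experiments run the same way:

```python
cohort3 = ag.filter_min_measurements(merged, 3)
stab = ag.run_stability(cohort3, ag.make_models(seed=0))
print(stab.summary[["model", "mean_delta_left", "mean_delta_right"]])
```

Dropping each patient's earliest measurement (left-censoring) inflates the
linear models' rates by ~0.25 mm/yr on average while deflating them under
right-censoring; the exponential mixed model's changes stay near zero —
the directional observation-window bias the package is designed to expose.

The same pipeline runs from the shell:

```sh
aagrowth run-all --seed 0 --outdir out/   # simulate -> fit -> all experiments
aagrowth simulate --seed 1 --out-prefix cohort
aagrowth fit cohort_measurements.csv --covariates cohort_covariates.csv --model all
```

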