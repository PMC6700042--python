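# hospvar

Between-hospital variation in risk-standardized survival outcomes after
surgery: a reusable analysis pipeline built around a 14-hospital glioblastoma
surgery cohort (2,409 adults, 2011–2014).

The pipeline covers:

* **Registry I/O and aggregation** (`hospvar.registry`) — patient-level CSV
  reading/writing, complete-case filtering on the model covariates (age,
  Karnofsky performance status, treatment year), observability logic for the
  30-day and 730-day horizons, and per-hospital summary tables.
* **Synthetic registry generation** (`hospvar.simulate`) — multi-hospital
  registries drawn from a piecewise-exponential proportional-hazards law with
  hospital frailties and administrative censoring; baseline hazards are
  calibrated so the marginal median survival hits a configurable target
  (default 10.2 months). All parameters are recorded as ground truth for
  recovery tests.
* **Hierarchical Bayesian survival model** (`hospvar.hazard`) — the
  log-Poisson counting-process representation of a piecewise-exponential Cox
  model with hospital random effects, sampled by a self-contained Hamiltonian
  Monte Carlo engine (`hospvar.mcmc`) with step-size and mass-matrix
  adaptation, plus R-hat/ESS diagnostics (`hospvar.diagnostics`). A
  fixed-effects variant estimates hazard ratios for hospital characteristics
  (log volume, academic setting, biopsy fraction) and is cross-checked
  against an independent Cox partial-likelihood implementation.
* **Risk standardization** (`hospvar.standardize`) — patient-specific
  expected survival functions at hospital random effect 0, hospital-level
  expected event counts (posterior median of per-draw sums, plug-in variant
  available) and observed-to-expected ratios.
* **Funnel plots** (`hospvar.funnel`) — 95%/99% Poisson control limits, both
  exact integer quantiles and smooth gamma/chi-square ("interpolated")
  limits, with outlier flagging and direction (better/worse).
* **Hospital-factor exploration** (`hospvar.factors`) — univariate logistic
  regressions of early death / 2-year survival on hospital characteristics
  (patient-level and binomially aggregated inputs give identical fits),
  boundary-volume and relative-effect computations.
* **Reporting** (`hospvar.report`) — Kaplan–Meier curves per hospital,
  observed-vs-expected survival panels and an end-to-end `run_pipeline`
  producing a deterministic report bundle.
* **Reference counts** (`hospvar.datasets`) — the built-in aggregate
  per-hospital table used in validation, plus an exact patient-level
  expansion of it.

## CLI

```bash
hospvar simulate --seed 1 --out registry.csv --truth truth.json
hospvar fit --registry registry.csv --mode hierarchical --seed 1 --out fit.json
hospvar fit --registry registry.csv --mode fixed --out hr.json
hospvar standardize --registry registry.csv --seed 1 --out ratios.csv
hospvar funnel --ratios ratios.csv --out funnel.png --flags flags.csv
hospvar explore --summary table1.csv --outcome early_death \
    --covariate log_volume --out explore.json
hospvar report --config pipeline.yaml --seed 1 --out out_dir
```

Exit codes: 0 ok, 1 validation error, 2 convergence failure. YAML configs map
directly onto the `GeneratorConfig` / `SamplerConfig` / `PipelineConfig`
dataclasses.

## Notes

* Analyses are in whole days from surgery (day 0); "death within 30 days"
  means `time_days <= 30`, "alive at 2 years" means no death by day 730.
* Default interval breaks `{0, 30, 90, 180, 270, 365, 545, 730, 1095, 1460}`
  include both outcome horizons, so horizon probabilities need no
  interpolation.
* Vague priors: Normal(0, 10) on coefficients and interval log-hazards,
  half-Cauchy(2.5) on the frailty standard deviation; age enters as
  (age − 61.4)/10, KPS as (KPS − 80)/10, treatment year as indicators with
  2011 reference; biopsy share enters the fixed-effects model as a 0–1
  fraction.
* Case volume in the logistic exploration defaults to the complete-case
  count (`volume_basis="complete"`); the all-registrations basis is one
  option away.
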