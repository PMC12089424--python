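# cogvar

Bayesian estimation of the proportion of variance in cognition explained by
biomarkers, accounting for individually varying outcome measurement error.

Cognitive composite scores are noisy estimates of a latent trait, and the
noise (the standard error of measurement, SEM) varies from person to person.
Ignoring it inflates residual variance and attenuates variance-explained
estimates. `cogvar` implements the full workflow:

- **`cogvar.irt`** — graded-response item banks, expected-a-posteriori (EAP)
  scoring with per-person SEM, test-information and SEM curves, and two
  built-in reference batteries (a 29-item high-information "memory-like"
  bank and a 6-item "visuospatial-like" bank with a ceiling effect).
- **`cogvar.cohort`** — a synthetic three-group (CN / MCI / AD) cohort
  generator with correlated biomarkers and known ground truth, plus standard
  biomarker preprocessing (ICV adjustment, WMH log transform, z-scoring).
- **`cogvar.models`** — two Bayesian normal linear models sharing one
  sampler: a standard fit (observed score as outcome) and a
  measurement-error fit (latent true score with known per-person error SD,
  marginalized analytically). Priors: flat on slopes, Student-t(3, 0, 2.5)
  on the intercept, Student-t(3, 0.4, 2.5) truncated to positives on the
  residual SD. Includes a deterministic profile-likelihood oracle and
  split-chain R-hat diagnostics.
- **`cogvar.decompose`** — per-draw proportion of variance explained
  (bounded in [0, 1) by construction), measurement-error variance via
  residual-variance subtraction, and paired-draw method contrasts with 95%
  credible intervals.
- **`cogvar.pipeline`** — the factorial study: per-biomarker and
  all-biomarker models, both methods, full sample and stratified by
  diagnostic group, with an R-hat convergence gate.

## CLI

```sh
# generate a scored synthetic cohort (1084 participants, 3 groups)
cogvar simulate --seed 1 --bank memory_like --out cohort.tsv --meta cohort.meta.json

# fit one model (standard, then accounting for measurement error)
cogvar fit --data cohort.tsv --biomarkers amyloid --no-me --out-prefix std
cogvar fit --data cohort.tsv --biomarkers amyloid --me    --out-prefix me

# combine the two fits into variance-explained summaries
cogvar decompose --data cohort.tsv --draws-standard std_draws.tsv \
    --draws-me me_draws.tsv --out decomposition.tsv

# or run the whole factorial study from a YAML config
cogvar run --config examples/run.yaml --out-dir results/
```

A minimal run config:

```yaml
mode: synthetic
bank: memory_like
biomarkers: [amyloid, hippocampus]
strata: [full, CN, MCI, AD]
sampler: {chains: 3, iterations: 1000, warmup: 200}
seed: 1
```

Input tables for real-data mode are tab-separated with one row per
participant and columns `score`, `sem`, one column per biomarker, and
optionally `group`, `phase`, `tracer`. Rows with missing values are dropped
(complete-case) with a logged report.

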