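# isomix

Bayesian tracer mixing models: estimate proportional source contributions
to mixtures (e.g., prey sources to consumer diets) from tracer data such
as stable isotopes or fatty-acid profiles.

Features:

* **Three mixture error structures** — residual-only, process-only
  (single-consumer designs), and process × multiplicative (a per-tracer
  term ξ that lets the process variance shrink or expand).
* **Three source-data treatments** — raw per-sample data (optionally with
  a full per-source tracer covariance), mean/SD/n summary statistics
  (fully Bayesian source updating), or fixed source moments.
* **Dirichlet priors on proportions** — generalist default (all α = 1),
  informative priors built from auxiliary counts with total-weight
  rescaling, and aggregation warnings when combining sources.
* **ILR-space covariates** — categorical and continuous fixed effects and
  hierarchical random effects on per-individual diet proportions via the
  isometric log-ratio transform.
* **Post-hoc analysis** — a-posteriori source combining, specialization
  index ε, covariate-grid predictions, mixing-polygon area diagnostic.
* **Model comparison** — WAIC and PSIS-LOO from per-consumer pointwise
  log likelihoods, with ΔLOOic and Akaike weights.
* Built-in adaptive Metropolis-within-Gibbs sampler (seed-reproducible),
  split-R̂/Geweke diagnostics, and a brute-force grid-posterior oracle
  for two-source models.

## Library quick start

```python
import numpy as np
from isomix import (
    read_mixture_table, read_source_table, read_discrimination_table,
    TracerDataset, ModelSpec, ErrorSpec, EffectDesign, McmcSettings,
    fit, posterior_summary, convergence_diagnostics,
)

mixture = read_mixture_table("consumers.csv", ["d13C", "d15N"],
                             continuous_columns=["Length"])
sources = read_source_table("sources.csv", "summary", ["d13C", "d15N"])
disc = read_discrimination_table("discrimination.csv", ["d13C", "d15N"],
                                 sources.source_names)
data = TracerDataset(mixture, sources, disc)

spec = ModelSpec(
    error=ErrorSpec("process_x_multiplicative"),
    effects=EffectDesign(fixed_continuous=("Length",)),
    source_treatment="summary",
)
draws = fit(spec, data, McmcSettings.preset("normal", seed=1))
print(convergence_diagnostics(draws))
print(posterior_summary(draws))
```

## CLI

`isomix` (or `python -m isomix.cli`) exposes:
`simulate`, `fit`, `diagnose`, `summarize`, `combine`, `epsilon`,
`predict`, `calc-area`, `compare`, `plot-prior`.

A fit is driven by a YAML config:

```yaml
mixture:
  path: consumers.csv
  tracers: [d13C, d15N]
  factors: [Sex, Size_class]     # categorical covariate columns
  random_flags: [false, false]   # parallel to factors; true = random effect
  continuous: [Length]
sources:
  path: sources.csv
  mode: summary                  # raw | summary
discrimination:
  path: discrimination.csv       # optional; omit for zero discrimination
model:
  error: process_x_multiplicative  # residual_only | process_only | ...
  effects:
    fixed_continuous: [Length]
  prior_alpha: null              # null = generalist (all 1)
  source_treatment: summary      # raw | summary | fixed
mcmc: {preset: normal, seed: 1, chains: 3}
output: run_out
```

```bash
isomix fit config.yaml --seed 1
isomix compare --model length=run_out/draws --model null=other/draws
isomix plot-prior --counts 30,8,25 --total-weight 3
```

## Input file dialect

Delimited text (comma or tab), decimal point only.

* **Mixture file**: one row per consumer; one column per tracer (e.g.,
  `d13C`), plus covariate columns.
* **Source summary file**: one row per source with columns `Source`,
  `Mean<tracer>`, `SD<tracer>`, optional `Conc<tracer>` (proportions in
  (0, 1]; divide percentages by 100) and `n`. Supplying a very large `n`
  (~10,000) effectively fixes the source moments.
* **Source raw file**: one row per source *sample* with `Source` and the
  tracer columns.
* **Discrimination file**: one row per source with `Source`,
  `Mean<tracer>`, `SD<tracer>`.

Factor levels are ordered by first appearance. A factor with exactly two
levels must be used as a fixed effect (a two-group random-effect SD is
unidentifiable).

## Notes on conventions

* The ILR basis is a fixed sequential binary partition in source-input
  order (coordinate *r* balances source *r* against sources *r+1..K*).
  Posterior proportions are basis-invariant; reported ILR coefficients
  are relative to this basis.
* Continuous covariates are centered and scaled to unit SD internally;
  predictions accept raw-scale values.
* ε is the normalized distance from the generalist barycenter,
  `sqrt(K/(K-1) * sum_k (p_k - 1/K)^2)`, 0 for a perfect generalist and
  1 at a simplex vertex.
* The default ξ prior is half-Cauchy(1) on the positive line;
  a chi-square family is available via `VariancePriorSpec`.
* `calc_area` returns the raw shoelace area of the discrimination-
  corrected source polygon (2 tracers only) and the fraction of
  consumers inside it; it is a diagnostic, not a likelihood component.
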