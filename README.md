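# gridshift

Biodiversity change on atlas grids: recorder-effort correction for
presence-only records, per-cell community metrics, and Bayesian spatial
GLMMs that quantify between-period change and attribute it to climate and
land-use drivers — exercised end to end on synthetic atlas data with known
truth.

## Who this is for

Ecologists and biodiversity-informatics researchers working with
atlas-style occurrence data: species lists per grid cell, aggregated into
recording periods decades apart, with recorder effort that is uneven,
unknown and confounded with real change. The package provides the full
analysis chain as an importable library (plus a thin `gridshift` CLI),
and — because real atlas datasets are access-restricted — a synthetic
atlas generator with a truth ledger, so every stage is testable without
any download.

## The models

**Recorder effort (Frescalo).** For each focal cell, neighbourhood-weighted
species frequencies `f` are rescaled as `f′ = 1 − (1 − f)^α` (the
frequency after α standard searches) and α solves

    φ(α) = Σ f′² / Σ f′ = 0.92,

the weighted mean frequency of a well-recorded cell. Effort is `1/α`.
Neighbourhoods are the 200 nearest cells re-ranked by land-use similarity,
keeping the 100 most similar, with smooth rank tapers as weights.

**Metrics.** Richness; neighbourhood beta diversity (mean Sørensen
dissimilarity `1 − 2|a∩b|/(|a|+|b|)` to the up-to-8 queen neighbours);
CTI (mean species temperature index of the species present, screened by a
`ceil(0.25 × max richness)` cutoff in the lowest-effort period); LCBD
(each cell's share of the Hellinger-transformed community-matrix variance,
summing to 1); turnover percentages.

**Trend models**, per metric and temporal scale, with the early period as
reference level of the factor T:

    SR_i  ~ Poisson(μ_i)  or  NegBin(μ_i, ɸ):  log μ_i  = α + η·T_i + Ω·log E_i + υ_i + ν_i
    BD_i  ~ Beta(μ_i, Ø):                    logit μ_i = α + κ·T_i + ψ·E_i
    CTI_i ~ Gamma(μ_i, θ):                     log μ_i  = α + τ·T_i + γ_i

where γ (and υ) are intrinsic-CAR (iCAR) spatial random effects on the
queen adjacency (precision Q = D − W, sum-to-zero), ν is an exchangeable
cell effect, and E is estimated effort. `exp(T coefficient)` is the
proportional change between periods.

**Attribution and LCBD models:**

    C_i ~ Gaussian(μ_i, σ²):   μ_i       = α + X_i·β + E_i·δ + γ_i
    L_i ~ Beta(μ_i, Φ):        logit μ_i = α + X_i·β + γ_i

with X the standardized changes in climate and land use, their two-way
interactions, baseline conditions and microclimatic heterogeneity
(orthogonalized by sequential regression), and per-cell posterior change
probabilities, marginal/conditional R² and a stepwise-R² decomposition by
variable group. Priors: N(0, 1000) fixed effects, flat intercept,
Gamma(1, 0.1) dispersion/precision hyperpriors, penalized-complexity
priors (P(σ > 1) = 0.01) on random-effect scales. Inference is
Metropolis-within-Gibbs MCMC with split-Rhat diagnostics (see
`docs/methods.md` for the samplers).

## Worked example

`examples/` holds one short script per capability. Fitting the trend
models on a 12×12-grid synthetic atlas (`examples/04_trend_models.py`):

```python
from gridshift import AnalysisConfig, generate_dataset
from gridshift.pipeline import run_effort, run_metrics, run_trend_models

cfg = AnalysisConfig(seed=1,
                     generator={"n_rows": 12, "n_cols": 12, "n_species": 80},
                     sampler={"chains": 2, "warmup": 400, "draws": 400})
ds = generate_dataset(seed=1, **cfg.generator)
effort = run_effort(ds, cfg)
metrics = run_metrics(ds, cfg)
trends = run_trend_models(cfg, metrics, effort, ds.grid)
```

prints

```
metric     scale  n_cells  change factor  [95% CI]        converged
richness   long      144     0.8546     [0.7606, 0.9731]  False
beta       long      144     1.5270     [1.2724, 1.8204]  True
cti        long      142     1.0154     [1.0066, 1.0243]  True
richness   short     144     1.0065     [0.9602, 1.0651]  False
beta       short     144     0.8858     [0.8407, 0.9361]  True
cti        short     144     1.0119     [1.0033, 1.0208]  True
```

Read each factor as the effort-adjusted proportional change from the
early to the late period: CTI rose by ~1.5% over the long term (the
credible interval excludes 1), consistent with the warming trend and the
warm-adapted species' positive temperature responses that the generator
planted; recorded richness rose strongly, but after the effort adjustment
the long-term model attributes it to rising recorder effort (and flags
its own period effect as not converged at this toy scale rather than
reporting it silently). The full pipeline — effort, metrics, trends,
attribution with stepwise R², LCBD models, tenfold cross-validation — runs
with one command:

```bash
gridshift all --seed 1 --out results/run1     # ~3 minutes at default scale
```

and writes per-stage CSVs, a JSON manifest and a log; the same seed
reproduces every output byte for byte.

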