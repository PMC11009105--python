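# Methods

`gridshift` analyses biodiversity change on a lattice of grid cells from
presence-only occurrence records collected in discrete recording periods.
This note documents the models and procedures the package implements, the
assumptions they rest on, the synthetic data the package uses to exercise
them, and the numerical choices inside the samplers.

## The analysis problem

Atlas-style recording schemes resurvey a national grid every few decades.
The records are presence-only, and how hard recorders searched each cell is
unknown and uneven in space and time, so raw between-period comparisons of
per-cell species lists confound real biodiversity change with recording
effort. The pipeline addresses this in four stages:

1. **Recorder effort** is estimated per cell and period from the records
   themselves (Frescalo).
2. **Community metrics** are computed per cell and period: species
   richness; beta diversity as the mean Sørensen dissimilarity between a
   focal cell and its up-to-eight queen neighbours (a decline is biotic
   homogenization); the community temperature index (CTI), the unweighted
   mean species temperature index (STI) of the species present; and LCBD,
   each cell's share of the total variance of the national community
   matrix (values sum to 1 across cells).
3. **Trend models** quantify proportional change in each metric between an
   early and a late period, adjusting for effort.
4. **Attribution models** regress each cell's metric change on changes in
   climate and land use, their two-way interactions, baseline conditions
   and microclimatic heterogeneity, with a spatially structured random
   effect; companion models link LCBD to habitat per period.

Two temporal scales are analysed throughout: *long* (first to third
period) and *short* (second to third). Only cells recorded in both
periods of a scale enter that scale's analyses.

## Recorder effort (Frescalo)

For each focal cell a neighbourhood is built from the `n_dist = 200`
nearest cells (centroid distance, focal first), re-ranked by land-use
similarity to the focal cell, of which the `n_sim = 100` most similar are
kept. Similarity is `1 − ‖p_focal − p_k‖₂/√2` on the land-use proportion
vectors; ties break by cell id, making the construction deterministic.
Each member's weight is the product of two quartic rank tapers,
`(1 − ((r−1)/n)²)⁴`, on the distance rank and the similarity rank — a
smooth decay from 1 at rank 1 to ~0 at the cutoff, isolated in one
function so an alternative taper can be substituted.

Neighbourhood-weighted species frequencies
`f(s) = Σ_k w_k·1[s recorded in k] / Σ_k w_k` are rescaled as
`f′ = 1 − (1 − f)^α`, the frequency expected after `α` independent
standard searches. The sampling-effort multiplier `α` solves
`φ(α) = Σ f′² / Σ f′ = 0.92`, the frequency-weighted mean frequency of a
well-recorded cell; recorder effort is `1/α`. The root is found by
bisection on log α in `[10⁻⁴, 10⁴]` to `|φ − 0.92| ≤ 10⁻⁶`; a solution
outside the bracket is returned with `converged = False` and is never
silently used downstream.

Two facts about the weighted statistic worth knowing: it is *not* strictly
monotone in α — with very short frequency vectors it can dip by up to
~0.02 at large α as rare species' rescaled frequencies catch up with
common ones (≲0.005 once ≥10 species carry positive frequency) — and for
the same reason the intuitive rule "removing records cannot raise
estimated effort" holds only up to those small dips. The unweighted mean
(available via `weighted=False`) is strictly monotone. The solver always
verifies the achieved φ, so a pathological crossing is reported rather
than silently wrong. Estimated effort is treated as a relative,
sign-correct measure — the synthetic benchmarks test recovery of effort
*contrasts*, not absolute calibration.

A benchmark-species variant reports the percentage of "benchmark" species
(the top `benchmark_fraction = 0.27` of species by local frequency in
each neighbourhood, at least one) that the cell actually recorded — the
coverage measure used for schemes whose effort is already classed as
high and even.

## Community metrics

* Sørensen dissimilarity `1 − 2|a∩b|/(|a|+|b|)`; undefined (missing) when
  both sets are empty.
* Neighbourhood beta diversity: mean Sørensen dissimilarity of the focal
  cell against each *recorded* queen neighbour; edge cells use the
  neighbours they have; no wraparound or imputation; cells with no usable
  neighbour are missing.
* CTI: unweighted mean STI over present species that have one; a
  configurable fraction of species may lack an STI, mirroring real trait
  tables.
* CTI screening: because effort cannot be regressed out of a
  composition-based index, cells with fewer than
  `ceil(0.25 × max richness)` species are excluded from CTI analyses,
  where the maximum is taken over cells in the period with the lowest
  mean estimated effort, and a cell must pass in both periods of a
  comparison. Ceiling is used: it is the strict reading of excluding
  cells below 25% (both of the rule's canonical worked examples,
  39 → 10 and 854 → 214, are consistent with it).
* LCBD: the community matrix (cells × species presences) is
  Hellinger-transformed by default (rows scaled to relative composition,
  square-rooted; `transform="none"` is available since the choice is a
  convention), columns centred, and each cell's LCBD is its share of the
  total sum of squares. Identical communities give a uniform 1/n with a
  warning.
* Turnover: percentages of the initial community gained and lost,
  `100·|t2∖t1|/|t1|` and `100·|t1∖t2|/|t1|`.

The change table joins late-minus-early differences in metrics,
covariates and effort to baseline (early-period) values, restricted to
cells recorded in both periods. Every explanatory column gets a
standardized (mean 0, sd 1) `z_` copy; all-missing columns (a land-use
category absent from the early map) and constant columns are skipped with
a warning.

## Bayesian spatial GLMMs

One model family per response:

| response | family | link | effort term | spatial effect |
|---|---|---|---|---|
| richness (counts) | Poisson or negative binomial | log | log E | iCAR + iid |
| beta diversity (0–1) | Beta | logit | E (natural) | none |
| CTI (positive) | Gamma | log | none (screening instead) | iCAR |
| metric change | Gaussian | identity | baseline E + ΔE (ΔE only for CTI) | iCAR (none for beta diversity) |
| LCBD (0–1) | Beta | logit | E (natural) | iCAR |

Variance conventions: negative binomial `var = μ + μ²/ɸ`; Beta
`var = μ(1−μ)/(precision+1)`; Gamma `var = μ²/θ`. The trend models code
the early period as the reference level of the period factor `T`, so
`exp(T coefficient)` is the proportional change to the late period
(`1 − exp(coef)` the proportional decrease when negative). Beta-family
responses of exactly 0 or 1 are nudged by `(y(n−1)+0.5)/n`, since Beta
support is open. Beta-diversity models carry no spatial term — the metric
is spatially autocorrelated by construction, and a spatial field would
absorb the signal.

**Spatial structure.** The intrinsic CAR (iCAR) prior puts precision
`Q = D − W` on the per-cell field over the queen adjacency graph, with an
exact sum-to-zero constraint per connected component (the null space of
Q). The richness models use the structured-plus-unstructured
decomposition — an iCAR field `υ` plus an exchangeable iid cell effect
`ν` — to keep separate control of overdispersion. Cells isolated in a
data subset are excluded from the field with a warning.

**Priors.** Fixed effects `N(0, σ² = 1000)`; effectively flat intercept
(`σ² = 10⁶`); Gamma(1, 0.1) on dispersion/precision hyperparameters;
Gamma(1, 5·10⁻⁵) on the Gaussian residual precision; and
penalized-complexity (exponential) priors on random-effect standard
deviations, default `P(σ > 1) = 0.01`, i.e. rate λ = −ln(0.01)/1. All are
configurable on `Priors`.

**Inference** is Metropolis-within-Gibbs MCMC, ≥4 chains by default:

* *Gaussian + iCAR with one row per cell* (the attribution models): the
  model is rotated into the eigenbasis of Q, where β and γ integrate out
  analytically and the marginal posterior of (log τ, log σ_γ) costs
  O(n·p) per evaluation. Slice sampling then moves freely along the long,
  nearly flat ridge that the residual sd and the field sd form when there
  is one observation per cell (centered Gibbs mixes pathologically there),
  and (β, γ) are redrawn exactly from their joint Gaussian conditional.
  The sum-to-zero constraint is exact: null eigenvectors carry no field.
* *Other Gaussian layouts*: conjugate block Gibbs for (β, γ), conjugate
  precision updates, Metropolis on the PC-priored scales, plus a
  non-centered ("interweaving") rescaling move for each field scale.
* *Non-Gaussian families*: adaptive joint random-walk Metropolis on β
  (proposal covariance adapted during warmup, initialised from a
  classical GLM/OLS fit) plus a per-coordinate refresh sweep; a chromatic
  update for the iCAR field — the adjacency graph is greedily coloured
  and all cells of one colour update simultaneously, since they are
  conditionally independent given the rest — with per-cell adapted steps;
  simultaneous independent Metropolis for the iid effects; log-scale
  random walks for dispersions and field scales with the same
  interweaving move. The field is re-centred every sweep with the mean
  folded into the intercept, which leaves the likelihood unchanged.

**Convergence** is monitored by split-chain potential scale reduction.
The `converged` flag covers the fixed-effect coefficients — the
parameters the analysis reports — at threshold 1.05. Variance components
of structured + iid decompositions are only jointly identified (the usual
BYM-type confounding; with one observation per cell the Gaussian residual
sd is ridge-flat against the field sd), so their R-hats are reported in
the hyperparameter table and warned about, but do not veto a fit whose
coefficients have converged. Non-convergence is always flagged on the
result object, never silent.

**Derived quantities.**

* Per-cell change probability: the share of posterior draws of the fitted
  mean change that are positive; summarised as the mean ± s.e. across
  cells, in percent.
* Marginal R²: variance of the fixed-effect linear predictor over the sum
  of fixed, spatial, iid and distribution-specific residual variances on
  the link scale (Gaussian σ²; log-link counts `ln(1 + 1/μ̄ (+ 1/ɸ))`;
  Gamma trigamma(θ); Beta `1/(μ̄(1−μ̄)(precision+1))` by the delta
  method). Conditional R² adds the random-effect variances to the
  numerator. Averaged over posterior draws.

## Collinearity and model comparison

Climate and land-use predictors are collinear by construction (land-use
proportions sum to one; changes correlate with baselines). Sequential
regression replaces predictor k by its residual on predictors 1..k−1 in a
configured order — default *causal priority*: baseline climate/land use,
microclimate, baseline biodiversity, then changes, then interactions — so
each coefficient reads as the effect of that variable's unique
contribution. Residual columns are re-standardized before fitting so
effect sizes stay comparable; a column that residualizes to numerical
zero (an exactly redundant category) is dropped with a warning. The same
orthogonalization is applied to the LCBD models' compositional land-use
block.

Interactions are products of the standardized change columns,
re-standardized.

The stepwise-R² analysis refits the change model cumulatively — base
model (spatial effect + effort terms), then changes in climate and land
use, interactions, baseline climate/land use, microclimatic
heterogeneity, baseline biodiversity, in that order — recording marginal
and conditional R² at each step; increments telescope to the total by
construction. A coefficient is flagged "no association" exactly when its
95% credible interval contains zero; no multiplicity correction is
applied, matching credible-interval reporting practice.

Tenfold cross-validation refits a model on ten 9/10 cell subsets
(sklearn KFold, seeded) and compares fold-wise coefficient means with the
full fit's intervals. A compatibility check correlates per-cell predicted
changes from the trend and attribution models and logs pass/warn at
Pearson r = 0.8; at desk scale this check usually *warns*, because the
trend model's per-cell predictions vary only through its spatial field
and effort terms — the check is a diagnostic, not a gate.

## Synthetic atlas generator

The generator is first-class, tested code: it defines the study
conditions under which every estimator is validated, with the full truth
retained in a `TruthLedger` (occupancy per period, true effort, generating
coefficients, seed; same seed ⇒ bit-identical ledger).

Defaults (the desk-scale study system): 20×20 grid, 120 species, three
periods T1–T3. Temperature and precipitation are Gaussian random fields
with exponential covariance `exp(−d/range)`, `range = 5` cell widths —
the simplest stationary field matching the smoothness the iCAR models
assume — around means of 9 °C and 900 mm, plus linear trends of
+0.8 °C and +40 mm from T1 to T3 with zero-mean spatially varying
anomalies (sd 0.25 °C, 25 mm) so that *change* varies across cells, as
real climate change does. Land use is a six-category composition (arable,
semi-natural grassland, improved grassland, forest, urban, water) from a
softmax of smooth fields; each period step converts semi-natural
grassland toward arable, improved grassland and urban (6%/6%/2% per step)
and forest toward urban (1%), with per-cell jitter on the realised
fractions so land-use change is not a deterministic function of the
baseline; compositions are renormalised (clamps counted and warned).
Microclimatic heterogeneity is a static positive surface. The
improved-grassland share can be masked in T1 to mirror a historical map
without that category.

Species occupancy: probability
`inverse-logit(logit(commonness) + Σ slope·z(covariate) + spatial field)`
per species, cell and period, standardising covariates against
first-period moments so trends shift occupancy; `commonness ~ Beta(2, 2.5)`
clipped to (0.02, 0.98); slopes `N(0, 0.25)` on temperature,
precipitation, arable, semi-natural grassland and urban, with the
temperature slope tied to the centred STI (coupling 0.6) so warm-adapted
species respond positively to warming — the construction that makes true
CTI rise under the warming trend. Each species gets its own spatial field
(sd 0.5). STIs are `N(9, 2)` °C with 5% missing.

Recording: a truly present species is recorded with probability
`1 − (1 − effort)^(4·commonness)` — effort acts as the per-search success
probability of repeated searches (which is what makes Frescalo's
"number of searches" multiplier meaningful), with commoner species
effectively exposed to more searches. Effort 1 records everything;
effort must lie in (0, 1]. The default effort surface is spatially patchy
(logit-normal around period means 0.5/0.65/0.8, sd 0.8, redrawn each
period) and rises toward the modern period, as coverage of real schemes
does. The recording process is this package's modelling assumption — the
analysis being emulated does not specify one generatively.

What the generator does **not** emulate: real geography (coastlines,
irregular cell availability), taxon-specific recording-scheme quirks,
observation heaping by popular sites, species' detectability differences
beyond commonness, temporal change within a recording period, and
taxonomic drift. Passing tests therefore demonstrate internal validity —
the estimators recover what the generator planted under the stated
assumptions — not field validity on any particular real atlas.

## Numerical choices and problem sizes

* α bisection: bracket [10⁻⁴, 10⁴], tolerance 10⁻⁶, ≤200 iterations.
* Gaussian-field Cholesky jitter 10⁻⁸; effort ε-guard 10⁻⁹ before logs.
* Sampler defaults: 4 chains, 700 warmup + 600 kept draws (reduced-draw
  configs are used for the stepwise-R² and cross-validation refits, which
  need point summaries rather than tail quantiles); split-Rhat
  threshold 1.05.
* MH proposals adapt by Robbins–Monro toward 0.234 (joint) / 0.44
  (scalar, per-cell) acceptance during warmup only; the β proposal
  covariance re-estimates every 100 warmup iterations after 200.
* Linear predictors are capped at 60 on log/logit scales inside
  likelihood evaluations so wild proposals reject cleanly instead of
  overflowing.
* Ties (distance, similarity, benchmark ranking) break by id order;
  everything derives from one integer seed through `SeedSequence` spawn
  keys, making pipeline outputs byte-identical across runs.
* Default problem sizes keep a full pipeline run (simulate → effort →
  metrics → trends → attribution → stepwise R² → LCBD → tenfold CV) at
  roughly three minutes on one core; the test suite's simulation studies
  use 10×10–20×20 grids with 2-chain samplers.

## Known limitations

* Effort is estimated, then plugged into the models as a covariate; the
  uncertainty of the Frescalo step is not propagated.
* The weighted φ statistic's small non-monotonicity (above) means α is a
  practical, not certified-unique, root; the achieved φ is always checked.
* The structured + iid variance split is only weakly identified from one
  observation per cell; interpret the individual variance components, and
  the conditional/marginal R² gap, qualitatively.
* Sequential regression makes coefficients order-dependent by design; the
  order is configuration, logged with every run.
* The Beta family treats LCBD values as conditionally independent given
  the linear predictor and field, but LCBD values are jointly constrained
  to sum to one.
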