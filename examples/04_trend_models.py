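"""Quantify biodiversity change between periods with spatial GLMMs.

One model per metric: the period factor's coefficient, on the log (or
logit) scale, converts into a proportional change via exp(coefficient);
recorder effort enters as a covariate (log scale for richness, natural
for beta diversity) and the CTI model relies on the richness screening
instead.  A structured (iCAR) spatial random effect soaks up residual
spatial autocorrelation.
"""

from gridshift import AnalysisConfig, generate_dataset
from gridshift.pipeline import run_effort, run_metrics, run_trend_models

cfg = AnalysisConfig(
    seed=1,
    generator={"n_rows": 12, "n_cols": 12, "n_species": 80},
    sampler={"chains": 2, "warmup": 400, "draws": 400},
)
ds = generate_dataset(seed=1, **cfg.generator)
effort = run_effort(ds, cfg)
metrics = run_metrics(ds, cfg)

trends = run_trend_models(cfg, metrics, effort, ds.grid)
print("metric     scale  n_cells  change factor  [95% CI]        "
      "converged")
for (metric, scale), tr in trends.items():
    ch = tr.change
    print(f"{metric:<10} {scale:<6} {tr.n_cells:>6}   "
          f"{ch.factor:>8.4f}     [{ch.factor_q025:.4f}, "
          f"{ch.factor_q975:.4f}]  {tr.posterior.converged}")
print("\na factor of 1.03 reads as +3% between the early and late "
      "period after adjusting for recorder effort; a CI excluding 1 "
      "flags a credible change.  The synthetic truth has warming-driven "
      "CTI increase, so the cti factor should sit above 1.")
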