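"""End-to-end analysis orchestration.

Chains the stages together — synthetic atlas generation, Frescalo effort,
community metrics, trend models (period-effect GLMMs per metric),
attribution models (Gaussian change models with iCAR spatial effects,
collinearity handled by sequential regression), stepwise R² by variable
group, LCBD models per period and tenfold cross-validation — with one
config object, one seed, logged decisions and reproducible outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold

from . import frescalo, metrics as cm, synthetic as syn
from .bayes import (ModelSpec, PosteriorSummary, Priors, SamplerConfig,
                    change_probability, fit, proportion_change,
                    r2_decomposition)
from .grid import GridDefinition
from .metrics import SCALE_PERIODS
from .records import PERIODS
from .synthetic import CLIMATE, LAND_USE, AtlasDataset

log = logging.getLogger("gridshift")

__all__ = ["AnalysisConfig", "TrendResult", "AttributionResult",
           "run_effort", "run_metrics", "run_trend_models",
           "sequential_residualization", "run_attribution", "stepwise_r2",
           "run_lcbd_models", "tenfold_cv", "run_all"]

# stepwise R² group ordering: changes first, then interactions, then
# baselines, microclimate and baseline biodiversity
STEPWISE_GROUPS = ["change_climate_landuse", "interactions",
                   "baseline_climate_landuse", "microclimate",
                   "baseline_biodiversity"]
# sequential-regression ordering: causal priority — baseline conditions
# precede changes, which precede their interactions
RESIDUALIZATION_ORDER = ["baseline_climate_landuse", "microclimate",
                         "baseline_biodiversity", "change_climate_landuse",
                         "interactions"]


@dataclass
class AnalysisConfig:
    """Everything one reproducible pipeline run needs."""

    taxon: str = "synthetic"
    scales: tuple = ("long", "short")
    metric_list: tuple = ("richness", "beta", "cti")
    richness_family: str = "poisson"   # negative_binomial for overdispersed
    cti_threshold_fraction: float = 0.25
    stepwise_groups: tuple = tuple(STEPWISE_GROUPS)
    residualization_order: tuple = tuple(RESIDUALIZATION_ORDER)
    sequential: bool = True            # residualize attribution predictors
    cv_folds: int = 10
    cv_metrics: tuple = ("richness",)  # metrics whose Eq-style change
                                       # model is cross-validated
    lcbd_transform: str = "hellinger"
    seed: int = 0
    generator: dict = field(default_factory=dict)   # synthetic overrides
    frescalo: dict = field(default_factory=lambda: {
        "phi": frescalo.PHI_DEFAULT,
        "n_dist": frescalo.N_DIST_DEFAULT,
        "n_sim": frescalo.N_SIM_DEFAULT,
        "weighted": True,
    })
    sampler: dict = field(default_factory=dict)     # SamplerConfig kwargs
    stepwise_sampler: dict = field(default_factory=lambda: {
        "chains": 2, "warmup": 400, "draws": 300})
    cv_sampler: dict = field(default_factory=lambda: {
        "chains": 2, "warmup": 400, "draws": 300})
    compatibility_threshold: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def make_sampler(self, overrides: dict | None = None) -> SamplerConfig:
        kw = dict(self.sampler)
        if overrides:
            kw.update(overrides)
        return SamplerConfig(**kw)


def _stage_seed(config: AnalysisConfig, key: int) -> int:
    """Deterministic per-stage integer seed derived from the config seed."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# stages

def run_effort(dataset: AtlasDataset, config: AnalysisConfig
               ) -> pd.DataFrame:
    """Frescalo effort (1/alpha) for every cell and period."""
    fcfg = config.frescalo
    weights = frescalo.build_neighbourhoods(
        dataset.grid, dataset.covariates,
        n_dist=fcfg["n_dist"], n_sim=fcfg["n_sim"])
    eff = frescalo.estimate_effort(
        dataset.records, weights, phi_target=fcfg["phi"],
        weighted=fcfg.get("weighted", True))
    n_bad = int((~eff["converged"]).sum())
    if n_bad:
        log.warning("%d cell/period effort estimates did not converge",
                    n_bad)
    return eff


def run_metrics(dataset: AtlasDataset, config: AnalysisConfig
                ) -> dict[str, pd.DataFrame]:
    """Per-period metric tables keyed by period label."""
    sti = dataset.pool.sti_table()
    periods = sorted(dataset.records["period"].unique(),
                     key=PERIODS.index)
    return {p: cm.compute_metrics(dataset.records, dataset.grid, sti, p,
                                  lcbd_transform=config.lcbd_transform)
            for p in periods}


@dataclass
class TrendResult:
    metric: str
    scale: str
    family: str
    n_cells: int
    posterior: PosteriorSummary
    change: "object"          # ProportionChange of the period effect
    cti_threshold: int | None = None
    row_cell_ids: np.ndarray | None = None  # data row -> cell_id


def _trend_data(metric, scale, metrics_by_period, effort, config):
    """Stacked two-period table for one trend model, filtered per metric."""
    early_p, late_p = SCALE_PERIODS[scale]
    early = metrics_by_period[early_p].set_index("cell_id")
    late = metrics_by_period[late_p].set_index("cell_id")
    cells = early.index.intersection(late.index)
    eff = effort.pivot(index="cell_id", columns="period", values="effort")
    threshold = None
    if metric == "cti":
        low_p = cm.lowest_effort_period(effort)
        max_rich = int(metrics_by_period[low_p]["richness"].max())
        threshold = cm.richness_threshold(
            max_rich, config.cti_threshold_fraction)
        keep = cm.cti_threshold_cells(metrics_by_period[early_p],
                                      metrics_by_period[late_p], threshold)
        cells = cells.intersection(keep)
        log.info("CTI threshold %d species (25%% of %d in %s); "
                 "%d cells retained", threshold, max_rich, low_p,
                 len(cells))
    rows = []
    for t, period in ((0.0, early_p), (1.0, late_p)):
        tab = (early if period == early_p else late).loc[cells]
        frame = pd.DataFrame({
            "cell_id": cells,
            "T": t,
            "response": tab[metric].to_numpy(),
            "effort": eff.loc[cells, period].to_numpy(),
        })
        rows.append(frame)
    data = pd.concat(rows, ignore_index=True)
    data = data.dropna(subset=["response", "effort"])
    # keep only cells observed (with finite response) in both periods
    counts = data.groupby("cell_id")["T"].count()
    keep = counts[counts == 2].index
    data = data[data["cell_id"].isin(keep)].reset_index(drop=True)
    data["log_effort"] = np.log(np.maximum(data["effort"], 1e-9))
    if (data["effort"] <= 0).any():
        log.warning("non-positive effort guarded with epsilon")
    return data, threshold


def run_trend_models(config: AnalysisConfig,
                     metrics_by_period: dict[str, pd.DataFrame],
                     effort: pd.DataFrame, grid: GridDefinition,
                     seed: int | None = None
                     ) -> dict[tuple[str, str], TrendResult]:
    """Period-effect GLMMs for every metric and temporal scale.

    Richness: Poisson or negative-binomial, log link, log-scale effort,
    structured + iid (Leroux-style) spatial effect.  Beta diversity: Beta
    family, logit link, natural-scale effort, no spatial term (the metric
    is spatially autocorrelated by construction).  CTI: Gamma, log link,
    no effort term but the richness-threshold cell filter, iCAR effect.
    The early period is the reference level, so exp(period coefficient)
    is the proportional change to the late period.
    """
    if seed is None:
        seed = _stage_seed(config, 3)
    results = {}
    for si, scale in enumerate(config.scales):
        for mi, metric in enumerate(config.metric_list):
            data, threshold = _trend_data(metric, scale, metrics_by_period,
                                          effort, config)
            if not len(data):
                raise ValueError(f"no cells left for {metric}/{scale}")
            if metric == "richness":
                spec = ModelSpec(config.richness_family, "response",
                                 ["T", "log_effort"],
                                 spatial_effect="icar_plus_iid",
                                 sampler=config.make_sampler())
            elif metric == "beta":
                spec = ModelSpec("beta", "response", ["T", "effort"],
                                 spatial_effect="none",
                                 sampler=config.make_sampler())
            else:  # cti
                spec = ModelSpec("gamma", "response", ["T"],
                                 spatial_effect="icar",
                                 sampler=config.make_sampler())
            res = fit(spec, data, grid=grid,
                      seed=seed + 10 * si + mi)
            change = proportion_change(res.coefficient_draws("T"))
            n_cells = data["cell_id"].nunique()
            log.info("trend %s/%s: n=%d, factor=%.4f, converged=%s",
                     metric, scale, n_cells, change.factor, res.converged)
            results[(metric, scale)] = TrendResult(
                metric=metric, scale=scale, family=spec.family,
                n_cells=n_cells, posterior=res, change=change,
                cti_threshold=threshold,
                row_cell_ids=data["cell_id"].to_numpy())
    return results


# ---------------------------------------------------------------------------
# attribution

def sequential_residualization(predictors: pd.DataFrame,
                               ordering: list[str] | None = None
                               ) -> tuple[pd.DataFrame, list[str]]:
    """Orthogonalize predictors by sequential least-squares regression.

    Column k is replaced by its residual from an ordinary least-squares
    regression on columns 1..k-1 (the first column is unchanged), making
    the output columns mutually orthogonal up to numerical tolerance.
    A column whose residual is numerically zero (perfectly collinear with
    its predecessors) is dropped and reported in the second return value.
    """
    cols = list(ordering) if ordering is not None \
        else list(predictors.columns)
    out = pd.DataFrame(index=predictors.index)
    dropped: list[str] = []
    basis: list[np.ndarray] = []
    for name in cols:
        v = predictors[name].to_numpy(float)
        if basis:
            B = np.column_stack(basis)
            coef, *_ = np.linalg.lstsq(B, v, rcond=None)
            v = v - B @ coef
        if float(v @ v) < 1e-10 * max(len(v), 1):
            dropped.append(name)
            log.warning("predictor %s is collinear with its predecessors; "
                        "dropped", name)
            continue
        out[name] = v
        basis.append(v)
    return out, dropped


def attribution_groups(change_table: pd.DataFrame, metric: str
                       ) -> dict[str, list[str]]:
    """Explanatory-variable groups present in a change table.

    Interactions are products of standardized climate-change and
    land-use-change columns, re-standardized (columns are added to the
    table in place when missing).
    """
    cols = set(change_table.columns)
    groups: dict[str, list[str]] = {}
    groups["change_climate_landuse"] = [
        f"z_d_{c}" for c in CLIMATE + LAND_USE if f"z_d_{c}" in cols]
    inter = []
    for cl in CLIMATE:
        for lu in LAND_USE:
            a, b = f"z_d_{cl}", f"z_d_{lu}"
            if a in cols and b in cols:
                name = f"z_ixn_{cl}_{lu}"
                if name not in change_table.columns:
                    prod = change_table[a] * change_table[b]
                    sd = prod.std(ddof=0)
                    change_table[name] = ((prod - prod.mean()) / sd
                                          if sd > 0 else 0.0)
                inter.append(name)
    groups["interactions"] = inter
    groups["baseline_climate_landuse"] = [
        f"z_baseline_{c}" for c in CLIMATE + LAND_USE
        if f"z_baseline_{c}" in cols]
    groups["microclimate"] = (["z_microclim_het"]
                              if "z_microclim_het" in cols else [])
    if metric == "cti":
        groups["baseline_biodiversity"] = []  # no baseline CTI term
    else:
        name = f"z_baseline_{metric}"
        groups["baseline_biodiversity"] = [name] if name in cols else []
    return groups


def _effort_terms(metric: str, change_table: pd.DataFrame) -> list[str]:
    # natural-scale effort controls; CTI models omit the baseline term
    terms = ["z_d_effort"]
    if metric != "cti" and "z_baseline_effort" in change_table.columns:
        terms = ["z_baseline_effort", "z_d_effort"]
    return [t for t in terms if t in change_table.columns]


@dataclass
class AttributionResult:
    metric: str
    scale: str
    n_cells: int
    coefficients: pd.DataFrame     # term, group, mean, CI, no_association
    r2_marginal: float
    r2_conditional: float
    cell_probabilities: pd.DataFrame  # cell_id, p_increase
    prob_increase_pct: float
    prob_increase_se_pct: float
    posterior: PosteriorSummary
    dropped: list[str]


def run_attribution(config: AnalysisConfig, change_table: pd.DataFrame,
                    grid: GridDefinition, metric: str, scale: str,
                    seed: int | None = None) -> AttributionResult:
    """Gaussian change model attributing metric change to drivers.

    Response: late-minus-early change in the metric.  Explanatory
    variables: standardized changes in climate and land use, their
    two-way interactions, baseline climate/land use, microclimatic
    heterogeneity and baseline biodiversity, plus recorder-effort
    controls.  Spatial iCAR effect for richness and CTI (beta diversity
    is spatially autocorrelated by construction, so its model has none).
    A coefficient is flagged "no association" when its 95% credible
    interval spans zero.
    """
    if seed is None:
        seed = _stage_seed(config, 4)
    table = change_table.copy()
    response = f"d_{metric}"
    groups = attribution_groups(table, metric)
    effort_cols = _effort_terms(metric, table)
    predictor_cols = [c for g in config.stepwise_groups
                      for c in groups.get(g, [])]
    used = [response] + effort_cols + predictor_cols + ["cell_id"]
    table = table.dropna(subset=[c for c in used if c in table.columns])

    if config.sequential:
        order = [c for g in config.residualization_order
                 for c in groups.get(g, [])]
        resid, dropped = sequential_residualization(table[order], order)
        # re-standardize so effect sizes stay comparable across terms
        resid = (resid - resid.mean()) / resid.std(ddof=0)
        for c in resid.columns:
            table[c] = resid[c]
        predictor_cols = [c for c in predictor_cols if c not in dropped]
    else:
        dropped = []

    spatial = "none" if metric == "beta" else "icar"
    spec = ModelSpec("gaussian", response, effort_cols + predictor_cols,
                     spatial_effect=spatial, sampler=config.make_sampler())
    res = fit(spec, table, grid=grid, seed=seed)

    coef = res.coefficients.copy()
    group_of = {c: g for g, cs in groups.items() for c in cs}
    for c in effort_cols:
        group_of[c] = "effort"
    coef["group"] = coef["term"].map(group_of).fillna("intercept")
    coef["no_association"] = (coef["q025"] <= 0) & (coef["q975"] >= 0)

    mu_draws = res.linpred_draws()   # identity link: fitted mean change
    # collapse rows to cells (one row per cell here)
    p_cell, mean_pct, se_pct = change_probability(mu_draws)
    cellprob = pd.DataFrame({"cell_id": table["cell_id"].to_numpy(),
                             "p_increase": p_cell})
    r2m, r2c = r2_decomposition(res)
    log.info("attribution %s/%s: n=%d, R2m=%.3f, R2c=%.3f, P(inc)=%.1f%%",
             metric, scale, len(table), r2m, r2c, mean_pct)
    return AttributionResult(
        metric=metric, scale=scale, n_cells=len(table),
        coefficients=coef, r2_marginal=r2m, r2_conditional=r2c,
        cell_probabilities=cellprob, prob_increase_pct=mean_pct,
        prob_increase_se_pct=se_pct, posterior=res, dropped=dropped)


def stepwise_r2(config: AnalysisConfig, change_table: pd.DataFrame,
                grid: GridDefinition, metric: str, scale: str,
                seed: int | None = None) -> pd.DataFrame:
    """R² trajectory as variable groups enter the change model in order.

    The base model holds only the spatial effect (where the metric's
    model has one) plus the recorder-effort terms; groups are then added
    cumulatively in ``config.stepwise_groups`` order, refitting and
    recording marginal and conditional R² at each step.
    """
    if seed is None:
        seed = _stage_seed(config, 5)
    table = change_table.copy()
    response = f"d_{metric}"
    groups = attribution_groups(table, metric)
    effort_cols = _effort_terms(metric, table)
    all_cols = [c for g in config.stepwise_groups for c in groups.get(g, [])]
    table = table.dropna(
        subset=[response] + effort_cols + all_cols + ["cell_id"])
    spatial = "none" if metric == "beta" else "icar"
    sampler = config.make_sampler(config.stepwise_sampler)

    rows = []
    current: list[str] = list(effort_cols)
    prev_m = prev_c = None
    for step, gname in enumerate(["base"] + list(config.stepwise_groups)):
        if gname != "base":
            cols = groups.get(gname, [])
            if not cols:
                log.info("stepwise %s/%s: group %s empty at this scale; "
                         "skipped", metric, scale, gname)
                continue
            current = current + cols
        spec = ModelSpec("gaussian", response, list(current),
                         spatial_effect=spatial, sampler=sampler)
        res = fit(spec, table, grid=grid, seed=seed + step)
        r2m, r2c = r2_decomposition(res)
        rows.append({"metric": metric, "scale": scale, "step": gname,
                     "r2_marginal": r2m, "r2_conditional": r2c,
                     "delta_marginal": (r2m - prev_m
                                        if prev_m is not None else np.nan),
                     "delta_conditional": (r2c - prev_c
                                           if prev_c is not None
                                           else np.nan)})
        prev_m, prev_c = r2m, r2c
    return pd.DataFrame(rows)


def run_lcbd_models(config: AnalysisConfig,
                    metrics_by_period: dict[str, pd.DataFrame],
                    covariates: syn.CovariateTable, effort: pd.DataFrame,
                    grid: GridDefinition, seed: int | None = None
                    ) -> dict[str, "LcbdResult"]:
    """Beta GLMMs linking LCBD to land use, climate and microclimate.

    One model per period: LCBD (logit link, iCAR spatial effect) against
    standardized climate, land-use and microclimatic-heterogeneity
    columns with natural-scale recorder effort as a control.
    """
    if seed is None:
        seed = _stage_seed(config, 6)
    eff = effort.pivot(index="cell_id", columns="period", values="effort")
    out = {}
    for pi, (period, mtab) in enumerate(sorted(metrics_by_period.items())):
        tab = mtab[["cell_id", "lcbd"]].copy()
        cov = covariates.period(period)
        tab = tab.join(cov, on="cell_id")
        tab["effort"] = tab["cell_id"].map(eff[period])
        predictors = []
        for c in CLIMATE + LAND_USE + ["microclim_het"]:
            col = tab[c]
            if col.isna().all():
                log.info("lcbd %s: %s absent; skipped", period, c)
                continue
            sd = col.std(ddof=0)
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"covariate {c} has no variance")
            tab[f"z_{c}"] = (col - col.mean()) / sd
            predictors.append(f"z_{c}")
        sd = tab["effort"].std(ddof=0)
        tab["z_effort"] = (tab["effort"] - tab["effort"].mean()) / sd
        tab = tab.dropna(subset=["lcbd", "z_effort"] + predictors)
        if tab["lcbd"].nunique() == 1:
            log.warning("lcbd %s: degenerate uniform LCBD; fit skipped",
                        period)
            continue
        if config.sequential:
            # land-use proportions are compositional (near-collinear);
            # sequential regression orthogonalizes them in column order
            resid, dropped = sequential_residualization(tab[predictors],
                                                        predictors)
            resid = (resid - resid.mean()) / resid.std(ddof=0)
            for c in resid.columns:
                tab[c] = resid[c]
            predictors = [c for c in predictors if c not in dropped]
        spec = ModelSpec("beta", "lcbd", ["z_effort"] + predictors,
                         spatial_effect="icar",
                         sampler=config.make_sampler())
        res = fit(spec, tab, grid=grid, seed=seed + pi)
        coef = res.coefficients.copy()
        coef["no_association"] = (coef["q025"] <= 0) & (coef["q975"] >= 0)
        out[period] = LcbdResult(period=period, n_cells=len(tab),
                                 coefficients=coef, posterior=res)
        log.info("lcbd %s: n=%d converged=%s", period, len(tab),
                 res.converged)
    return out


@dataclass
class LcbdResult:
    period: str
    n_cells: int
    coefficients: pd.DataFrame
    posterior: PosteriorSummary


def tenfold_cv(spec: ModelSpec, data: pd.DataFrame,
               grid: GridDefinition | None, seed: int,
               folds: int = 10) -> pd.DataFrame:
    """Coefficient stability under k-fold refitting.

    Cells are split into ``folds`` equal parts; the model is refitted on
    each nine-tenths and the fold-wise posterior means are returned next
    to the full-fit posterior mean and credible interval.  Fold
    assignment is reproducible from ``seed``.
    """
    if len(data) < folds:
        raise ValueError("need at least as many rows as folds")
    full = fit(spec, data, grid=grid, seed=seed)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    cells = data["cell_id"].unique() if spec.spatial_effect != "none" \
        else np.arange(len(data))
    rows = []
    for k, (train_idx, _test) in enumerate(kf.split(cells)):
        if spec.spatial_effect != "none":
            keep = set(cells[train_idx])
            sub = data[data["cell_id"].isin(keep)]
        else:
            sub = data.iloc[train_idx]
        res = fit(spec, sub, grid=grid, seed=seed + 1000 + k)
        for term in res.terms:
            c = res.coefficient(term)
            rows.append({"fold": k + 1, "term": term,
                         "fold_mean": c["mean"]})
    cv = pd.DataFrame(rows)
    fullc = full.coefficients[["term", "mean", "q025", "q975"]].rename(
        columns={"mean": "full_mean"})
    return cv.merge(fullc, on="term", how="left")


# ---------------------------------------------------------------------------
# full run

def _compatibility_check(trend: TrendResult, attrib: AttributionResult,
                         threshold: float) -> tuple[float, bool]:
    """Correlate per-cell predicted change from the trend and change models.

    The trend model predicts each cell's metric in both periods; the
    difference of its fitted means is compared (Pearson r) with the
    change model's fitted mean change.
    """
    res = trend.posterior
    mu = res.fitted_mean_draws().mean(axis=0)
    df = pd.DataFrame({"mu": mu, "T": res.X[:, res.terms.index("T")],
                       "cell_id": trend.row_cell_ids})
    wide = df.pivot_table(index="cell_id", columns="T", values="mu")
    pred_trend = (wide[1.0] - wide[0.0]).rename("trend")
    att = attrib.posterior
    mu_att = att.linpred_draws().mean(axis=0)
    att_cells = attrib.cell_probabilities["cell_id"].to_numpy()
    pred_att = pd.Series(mu_att, index=att_cells, name="attrib")
    joined = pd.concat([pred_trend, pred_att], axis=1).dropna()
    if len(joined) < 3:
        return np.nan, False
    r = float(np.corrcoef(joined["trend"], joined["attrib"])[0, 1])
    return r, r >= threshold


def run_all(config: AnalysisConfig, outdir=None,
            dataset: AtlasDataset | None = None) -> dict:
    """Execute the complete synthetic-atlas analysis.

    simulate -> effort -> metrics -> change tables -> trend models ->
    attribution (+ stepwise R², change probabilities) -> LCBD models ->
    cross-validation.  Writes per-stage CSVs and a JSON manifest when
    ``outdir`` is given; returns all results in memory.
    """
    t_start = time.time()
    if dataset is None:
        gen_seed = _stage_seed(config, 1)
        dataset = syn.generate_dataset(seed=gen_seed, **config.generator)
        log.info("simulated dataset: %d cells, %d species, %d records",
                 dataset.grid.n_cells, len(dataset.pool.table),
                 len(dataset.records))

    effort = run_effort(dataset, config)
    metrics_by_period = run_metrics(dataset, config)
    changes = {scale: cm.build_change_table(metrics_by_period,
                                            dataset.covariates, effort,
                                            scale=scale)
               for scale in config.scales}

    trends = run_trend_models(config, metrics_by_period, effort,
                              dataset.grid)

    attributions = {}
    stepwise = []
    for scale in config.scales:
        for metric in config.metric_list:
            table = changes[scale]
            if metric == "cti":
                thr = trends[("cti", scale)].cti_threshold
                early_p, late_p = SCALE_PERIODS[scale]
                keep = cm.cti_threshold_cells(metrics_by_period[early_p],
                                              metrics_by_period[late_p],
                                              thr)
                table = table[table["cell_id"].isin(keep)]
            attributions[(metric, scale)] = run_attribution(
                config, table, dataset.grid, metric, scale)
            stepwise.append(stepwise_r2(config, table, dataset.grid,
                                        metric, scale))
    stepwise_df = pd.concat(stepwise, ignore_index=True)

    lcbd_models = run_lcbd_models(config, metrics_by_period,
                                  dataset.covariates, effort, dataset.grid)

    # turnover between the periods of each scale
    turnover_tabs = {}
    for scale in config.scales:
        early_p, late_p = SCALE_PERIODS[scale]
        from .records import species_sets
        s_early = species_sets(dataset.records, early_p)
        s_late = species_sets(dataset.records, late_p)
        rows = []
        for cell in sorted(set(s_early) & set(s_late)):
            gained, lost = cm.turnover(s_early[cell], s_late[cell])
            rows.append({"cell_id": cell, "pct_gained": gained,
                         "pct_lost": lost})
        turnover_tabs[scale] = pd.DataFrame(rows)

    # cross-validation of selected attribution models
    cv_tables = {}
    cv_seed = _stage_seed(config, 7)
    for scale in config.scales:
        for metric in config.cv_metrics:
            spec = attributions[(metric, scale)].posterior.spec
            spec_cv = ModelSpec(spec.family, spec.response,
                                spec.fixed_effects,
                                spatial_effect=spec.spatial_effect,
                                sampler=config.make_sampler(
                                    config.cv_sampler))
            cv_tables[(metric, scale)] = tenfold_cv(
                spec_cv, _attribution_data(config, changes[scale], metric),
                dataset.grid, seed=cv_seed, folds=config.cv_folds)

    compat = {}
    for scale in config.scales:
        for metric in config.metric_list:
            r, ok = _compatibility_check(
                trends[(metric, scale)], attributions[(metric, scale)],
                config.compatibility_threshold)
            compat[(metric, scale)] = {"pearson_r": r, "pass": ok}
            log.log(logging.INFO if ok else logging.WARNING,
                    "compatibility %s/%s: r=%.3f (%s)", metric, scale,
                    r if np.isfinite(r) else -9,
                    "pass" if ok else "warn")

    results = {
        "dataset": dataset, "effort": effort,
        "metrics_by_period": metrics_by_period, "changes": changes,
        "trends": trends, "attributions": attributions,
        "stepwise_r2": stepwise_df, "lcbd_models": lcbd_models,
        "turnover": turnover_tabs, "cv": cv_tables,
        "compatibility": compat,
        "elapsed_s": time.time() - t_start,
    }
    if outdir is not None:
        _write_outputs(config, results, Path(outdir))
    log.info("pipeline finished in %.1f s", results["elapsed_s"])
    return results


def _attribution_data(config, change_table, metric):
    """Rebuild the (possibly residualized) attribution data table."""
    table = change_table.copy()
    groups = attribution_groups(table, metric)
    effort_cols = _effort_terms(metric, table)
    predictor_cols = [c for g in config.stepwise_groups
                      for c in groups.get(g, [])]
    table = table.dropna(subset=[f"d_{metric}"] + effort_cols
                         + predictor_cols + ["cell_id"])
    if config.sequential:
        order = [c for g in config.residualization_order
                 for c in groups.get(g, [])]
        resid, _ = sequential_residualization(table[order], order)
        resid = (resid - resid.mean()) / resid.std(ddof=0)
        for c in resid.columns:
            table[c] = resid[c]
    return table


def _write_outputs(config: AnalysisConfig, results: dict,
                   outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ds: AtlasDataset = results["dataset"]
    ds.grid.to_csv(outdir / "grid.csv")
    ds.covariates.to_csv(outdir / "covariates.csv")
    ds.records.to_csv(outdir / "records.csv", index=False)
    ds.pool.to_csv(outdir / "species_pool.csv")
    results["effort"].to_csv(outdir / "effort.csv", index=False)
    for period, tab in results["metrics_by_period"].items():
        tab.to_csv(outdir / f"metrics_{period}.csv", index=False)
    for scale, tab in results["changes"].items():
        tab.to_csv(outdir / f"changes_{scale}.csv", index=False)

    trows = []
    for (metric, scale), tr in results["trends"].items():
        ch = tr.change
        trows.append({
            "metric": metric, "scale": scale, "family": tr.family,
            "n_cells": tr.n_cells, "factor": ch.factor,
            "percent_change": ch.percent_change,
            "factor_q025": ch.factor_q025, "factor_q975": ch.factor_q975,
            "converged": tr.posterior.converged,
            "cti_threshold": tr.cti_threshold,
        })
    pd.DataFrame(trows).to_csv(outdir / "trends.csv", index=False)

    arows = []
    for (metric, scale), att in results["attributions"].items():
        tab = att.coefficients.copy()
        tab.insert(0, "metric", metric)
        tab.insert(1, "scale", scale)
        arows.append(tab)
        att.cell_probabilities.to_csv(
            outdir / f"change_probability_{metric}_{scale}.csv",
            index=False)
    pd.concat(arows, ignore_index=True).to_csv(
        outdir / "attribution_coefficients.csv", index=False)
    summary = pd.DataFrame([
        {"metric": m, "scale": s, "n_cells": a.n_cells,
         "r2_marginal": a.r2_marginal, "r2_conditional": a.r2_conditional,
         "prob_increase_pct": a.prob_increase_pct,
         "prob_increase_se_pct": a.prob_increase_se_pct}
        for (m, s), a in results["attributions"].items()])
    summary.to_csv(outdir / "attribution_summary.csv", index=False)
    results["stepwise_r2"].to_csv(outdir / "stepwise_r2.csv", index=False)

    lrows = []
    for period, lr in results["lcbd_models"].items():
        tab = lr.coefficients.copy()
        tab.insert(0, "period", period)
        lrows.append(tab)
    if lrows:
        pd.concat(lrows, ignore_index=True).to_csv(
            outdir / "lcbd_coefficients.csv", index=False)
    for scale, tab in results["turnover"].items():
        tab.to_csv(outdir / f"turnover_{scale}.csv", index=False)
    for (metric, scale), tab in results["cv"].items():
        tab.to_csv(outdir / f"cv_{metric}_{scale}.csv", index=False)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "elapsed_s": results["elapsed_s"],
        "compatibility": {f"{m}_{s}": v for (m, s), v in
                          results["compatibility"].items()},
        "n_records": int(len(ds.records)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    config.to_yaml(outdir / "config.yaml")
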