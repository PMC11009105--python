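"""Bayesian GLMMs on lattice data with intrinsic-CAR spatial effects.

Five response families cover the analysis: Poisson and negative-binomial
counts (species richness), Beta proportions (neighbourhood beta diversity
and LCBD), Gamma positives (CTI) and Gaussian (metric changes).  Spatial
structure enters as an intrinsic conditional autoregressive (iCAR) random
effect over the queen-adjacency graph — precision Q = D - W with a
sum-to-zero constraint — optionally paired with an exchangeable iid cell
effect (the structured + unstructured decomposition used to absorb count
overdispersion).

Priors follow the conventions of the analysis: fixed effects N(0, 1000),
an effectively flat intercept, Gamma(1, 0.1) on dispersion/precision
hyperparameters, and penalized-complexity (exponential) priors on
random-effect standard deviations with P(sigma > 1) = 0.01 by default.

Inference is Metropolis-within-Gibbs MCMC (see :mod:`gridshift._mcmc`);
convergence is monitored with split-chain potential scale reduction
across >= 4 chains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _mcmc
from .grid import GridDefinition

FAMILY_LINKS = {
    "poisson": "log",
    "negative_binomial": "log",
    "beta": "logit",
    "gamma": "log",
    "gaussian": "identity",
}

__all__ = ["Priors", "SamplerConfig", "ModelSpec", "PrecisionStructure",
           "PosteriorSummary", "build_icar", "fit", "proportion_change",
           "ProportionChange", "change_probability", "r2_decomposition",
           "FAMILY_LINKS"]


@dataclass
class Priors:
    """Prior settings shared by all model families."""

    beta_var: float = 1000.0        # N(0, sigma^2=1000) fixed effects
    intercept_var: float = 1e6      # effectively flat intercept
    disp_shape: float = 1.0         # Gamma(1, 0.1) on dispersion/precision
    disp_rate: float = 0.1
    gauss_prec_shape: float = 1.0   # Gamma on Gaussian residual precision
    gauss_prec_rate: float = 5e-5
    pc_u: float = 1.0               # PC prior: P(sigma > pc_u) = pc_alpha
    pc_alpha: float = 0.01

    def pc_lambda(self) -> float:
        return -math.log(self.pc_alpha) / self.pc_u


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 700
    draws: int = 600
    rhat_threshold: float = 1.05


@dataclass
class ModelSpec:
    """What to fit: family, response, fixed effects, spatial structure.

    ``fixed_effects`` are column names in the data table (enter a
    log-scale effort term by passing a column that already holds log E).
    ``spatial_effect`` is one of ``none``, ``icar``, ``icar_plus_iid``.
    """

    family: str
    response: str
    fixed_effects: list[str]
    spatial_effect: str = "none"
    cell_col: str = "cell_id"
    priors: Priors = field(default_factory=Priors)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def __post_init__(self) -> None:
        if self.family not in FAMILY_LINKS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.spatial_effect not in ("none", "icar", "icar_plus_iid"):
            raise ValueError(
                f"unknown spatial_effect {self.spatial_effect!r}")

    @property
    def link(self) -> str:
        return FAMILY_LINKS[self.family]


@dataclass
class PrecisionStructure:
    """iCAR building blocks for a set of cells: Q = D - W.

    Q is symmetric positive semi-definite; its null space is spanned by
    the indicator of each connected component, hence the sum-to-zero
    constraint per component.
    """

    cell_ids: list[str]
    W: sp.csr_matrix
    D: np.ndarray
    Q: sp.csr_matrix
    component_labels: np.ndarray
    n_components: int
    isolated: list[str]
    sum_to_zero: bool = True


def build_icar(grid: GridDefinition,
               cells: list[str] | None = None) -> PrecisionStructure:
    """Queen-adjacency iCAR precision structure, optionally on a subset.

    Cells with no neighbour inside the subset are flagged ``isolated``
    (they get no spatial smoothing) with a warning.
    """
    if cells is None:
        cells = grid.cell_ids
    index = {c: i for i, c in enumerate(cells)}
    rows, cols = [], []
    for c in cells:
        for nb in grid.neighbours[c]:
            j = index.get(nb)
            if j is not None:
                rows.append(index[c])
                cols.append(j)
    n = len(cells)
    W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    D = np.asarray(W.sum(axis=1)).ravel()
    Q = sp.diags(D) - W
    n_comp, labels = _mcmc.graph_components(W)
    isolated = [cells[i] for i in np.flatnonzero(D == 0)]
    if isolated:
        warnings.warn(f"{len(isolated)} isolated cells excluded from the "
                      "spatial effect")
    return PrecisionStructure(cell_ids=list(cells), W=W, D=D,
                              Q=Q.tocsr(), component_labels=labels,
                              n_components=n_comp, isolated=isolated)


# ---------------------------------------------------------------------------
# results container

@dataclass
class PosteriorSummary:
    """Posterior summaries and draws for one fitted model."""

    spec: ModelSpec
    terms: list[str]
    coefficients: pd.DataFrame       # term, mean, sd, q025, q975, p_positive, rhat
    hyperparameters: pd.DataFrame
    beta_draws: np.ndarray           # (chains, draws, p)
    hyper_draws: dict[str, np.ndarray]
    gamma_draws: np.ndarray | None
    nu_draws: np.ndarray | None
    cell_ids: list[str] | None
    row_cells: np.ndarray | None
    X: np.ndarray
    y: np.ndarray
    converged: bool
    messages: list[str]

    @property
    def n_draws(self) -> int:
        c, d, _ = self.beta_draws.shape
        return c * d

    def beta_flat(self) -> np.ndarray:
        c, d, p = self.beta_draws.shape
        return self.beta_draws.reshape(c * d, p)

    def linpred_draws(self) -> np.ndarray:
        """(total draws, n_rows) posterior draws of the linear predictor."""
        lp = self.beta_flat() @ self.X.T
        if self.gamma_draws is not None:
            lp = lp + self.gamma_draws[:, self.row_cells]
        if self.nu_draws is not None:
            lp = lp + self.nu_draws[:, self.row_cells]
        return lp

    def fitted_mean_draws(self) -> np.ndarray:
        lp = self.linpred_draws()
        link = self.spec.link
        if link == "log":
            return np.exp(lp)
        if link == "logit":
            return 1.0 / (1.0 + np.exp(-lp))
        return lp

    def coefficient(self, term: str) -> pd.Series:
        return self.coefficients.set_index("term").loc[term]

    def coefficient_draws(self, term: str) -> np.ndarray:
        return self.beta_flat()[:, self.terms.index(term)]

    def no_association(self, term: str) -> bool:
        """True when the 95% credible interval contains zero."""
        row = self.coefficient(term)
        return bool(row["q025"] <= 0.0 <= row["q975"])


def _validate_response(family: str, y: np.ndarray) -> np.ndarray:
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains missing values")
    if family in ("poisson", "negative_binomial"):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError(f"{family} requires non-negative counts")
    elif family == "beta":
        if np.any((y < 0) | (y > 1)):
            raise ValueError("beta requires responses in [0, 1]")
        if np.any((y == 0) | (y == 1)):
            n = y.size
            y = (y * (n - 1) + 0.5) / n  # open the support
            warnings.warn("beta responses of 0/1 nudged into (0, 1)")
    elif family == "gamma":
        if np.any(y <= 0):
            raise ValueError("gamma requires strictly positive responses")
    return y


def _init_values(family, y, X):
    """Starting point and proposal covariance from a cheap classical fit."""
    import statsmodels.api as sm

    disp = 1.0
    try:
        if family == "poisson":
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        elif family == "negative_binomial":
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            mu = res.fittedvalues
            excess = max(np.mean(((y - mu) ** 2 - mu) / mu ** 2), 1e-3)
            disp = 1.0 / excess
        elif family == "gamma":
            res = sm.GLM(y, X, family=sm.families.Gamma(
                sm.families.links.Log())).fit()
            disp = max(1.0 / res.scale, 1e-2)
        elif family == "beta":
            z = np.log(y / (1.0 - y))
            res = sm.OLS(z, X).fit()
            disp = max(1.0 / max(res.mse_resid, 1e-4), 2.0)
        else:  # gaussian
            res = sm.OLS(y, X).fit()
        beta0 = np.asarray(res.params, float)
        cov = np.asarray(res.cov_params(), float)
        cov = cov + 1e-8 * np.eye(cov.shape[0])
    except Exception:  # fall back to a neutral start
        beta0 = np.zeros(X.shape[1])
        cov = np.eye(X.shape[1]) * 0.01
    return beta0, cov, disp


def fit(spec: ModelSpec, data: pd.DataFrame,
        grid: GridDefinition | None = None,
        seed: int = 0) -> PosteriorSummary:
    """Fit one spatial GLMM by MCMC and summarise its posterior.

    ``data`` must contain the response, every fixed-effect column and
    (for spatial models) the cell column; ``grid`` supplies the adjacency
    for the spatial effect.  All randomness is derived from ``seed``.
    Non-convergence (split-Rhat above the threshold on any reported
    parameter) is flagged on the result, never silently ignored.
    """
    cols = [spec.response] + spec.fixed_effects
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns: {missing}")
    sub = data[cols + ([spec.cell_col] if spec.spatial_effect != "none"
                       else [])].copy()
    if sub[cols].isna().any().any():
        raise ValueError("missing values in model columns; filter first")

    y = _validate_response(spec.family, sub[spec.response].to_numpy(float))
    X = np.column_stack([np.ones(len(sub))]
                        + [sub[c].to_numpy(float)
                           for c in spec.fixed_effects])
    terms = ["intercept"] + list(spec.fixed_effects)

    messages: list[str] = []
    if spec.spatial_effect != "none":
        if grid is None:
            raise ValueError("spatial models need a grid")
        cells = list(dict.fromkeys(sub[spec.cell_col]))
        structure = build_icar(grid, cells)
        cell_index = {c: i for i, c in enumerate(cells)}
        A = sub[spec.cell_col].map(cell_index).to_numpy()
    else:
        structure = None
        cells = None
        A = None

    beta0, prop_cov, disp0 = _init_values(spec.family, y, X)
    ss = np.random.SeedSequence(seed).spawn(spec.sampler.chains)
    chains = []
    for k in range(spec.sampler.chains):
        rng = np.random.default_rng(ss[k])
        b0 = beta0 + 0.05 * rng.standard_normal(beta0.size)
        if spec.family == "gaussian":
            chains.append(_mcmc.run_gaussian_chain(
                y, X, A,
                structure.Q if structure is not None else None,
                structure.W if structure is not None else None,
                structure.component_labels if structure is not None else None,
                structure.n_components if structure is not None else 1,
                spec.spatial_effect, spec.priors,
                spec.sampler.warmup, spec.sampler.draws, rng,
                init_beta=b0))
        else:
            chains.append(_mcmc.run_glmm_chain(
                spec.family, y, X, A,
                structure.W if structure is not None else None,
                structure.component_labels if structure is not None else None,
                structure.n_components if structure is not None else 1,
                spec.spatial_effect, spec.priors,
                spec.sampler.warmup, spec.sampler.draws, rng,
                init_beta=b0, init_disp=disp0, prop_cov=prop_cov))

    p = X.shape[1]
    beta_draws = np.stack([c["beta"] for c in chains])  # chains,draws,p
    hyper_draws: dict[str, np.ndarray] = {}
    if spec.family == "gaussian":
        hyper_draws["sigma"] = np.stack([c["sigma"] for c in chains])
    else:
        if spec.family != "poisson":
            hyper_draws["dispersion"] = np.stack([c["disp"] for c in chains])
    if spec.spatial_effect != "none":
        hyper_draws["sigma_gamma"] = np.stack([c["sigma_gamma"]
                                               for c in chains])
    if spec.spatial_effect == "icar_plus_iid":
        hyper_draws["sigma_nu"] = np.stack([c["sigma_nu"] for c in chains])

    flat = beta_draws.reshape(-1, p)
    rows = []
    for j, term in enumerate(terms):
        d = flat[:, j]
        rows.append({
            "term": term, "mean": d.mean(), "sd": d.std(ddof=1),
            "q025": np.quantile(d, 0.025), "q975": np.quantile(d, 0.975),
            "p_positive": float(np.mean(d > 0)),
            "rhat": _mcmc.split_rhat(beta_draws[:, :, j]),
        })
    coef = pd.DataFrame(rows)

    hrows = []
    for name, d in hyper_draws.items():
        fd = d.ravel()
        hrows.append({
            "parameter": name, "mean": fd.mean(), "sd": fd.std(ddof=1),
            "q025": np.quantile(fd, 0.025), "q975": np.quantile(fd, 0.975),
            "rhat": _mcmc.split_rhat(d),
        })
    hyper = pd.DataFrame(hrows)

    # the reported (inferential) parameters are the fixed effects; the
    # variance components of structured+iid decompositions are only
    # jointly identified, so their Rhats are reported but only warned on
    crh = coef["rhat"].to_numpy()
    crh = crh[np.isfinite(crh)]
    converged = bool(np.all(crh < spec.sampler.rhat_threshold))
    if not converged:
        messages.append(
            f"max fixed-effect split-Rhat {np.max(crh):.3f} exceeds "
            f"{spec.sampler.rhat_threshold}")
    if len(hyper):
        hrh = hyper["rhat"].to_numpy()
        bad = hyper["parameter"][np.isfinite(hrh)
                                 & (hrh >= spec.sampler.rhat_threshold)]
        if len(bad):
            messages.append("hyperparameters mixing slowly: "
                            + ", ".join(bad))

    gamma_draws = nu_draws = None
    if spec.spatial_effect != "none":
        gamma_draws = np.concatenate([c["gamma"] for c in chains])
    if spec.spatial_effect == "icar_plus_iid":
        nu_draws = np.concatenate([c["nu"] for c in chains])

    return PosteriorSummary(
        spec=spec, terms=terms, coefficients=coef, hyperparameters=hyper,
        beta_draws=beta_draws, hyper_draws=hyper_draws,
        gamma_draws=gamma_draws, nu_draws=nu_draws,
        cell_ids=cells, row_cells=A, X=X, y=y,
        converged=converged, messages=messages)


# ---------------------------------------------------------------------------
# derived quantities

@dataclass
class ProportionChange:
    """Relative change implied by a log-link period coefficient."""

    factor: float            # exp(posterior mean coefficient)
    percent_change: float    # 100 * (factor - 1)
    increase: float | None   # factor when coef > 0 else None
    decrease: float | None   # 1 - factor when coef < 0 else None
    factor_draws_mean: float
    factor_q025: float
    factor_q975: float


def proportion_change(coef_draws: np.ndarray) -> ProportionChange:
    """Turn posterior draws of a log-link period coefficient into change.

    The multiplicative change factor is exp(coefficient): applied to the
    posterior mean for the headline number, and to every draw for
    uncertainty.  A positive coefficient reads as a proportional increase
    of exp(coef); a negative one as a proportional decrease 1 - exp(coef).
    """
    coef_draws = np.asarray(coef_draws, float)
    mean_coef = coef_draws.mean()
    factor = float(np.exp(mean_coef))
    fdraws = np.exp(coef_draws)
    return ProportionChange(
        factor=factor,
        percent_change=100.0 * (factor - 1.0),
        increase=factor if mean_coef > 0 else None,
        decrease=1.0 - factor if mean_coef < 0 else None,
        factor_draws_mean=float(fdraws.mean()),
        factor_q025=float(np.quantile(fdraws, 0.025)),
        factor_q975=float(np.quantile(fdraws, 0.975)),
    )


def change_probability(mu_draws: np.ndarray
                       ) -> tuple[np.ndarray, float, float]:
    """Per-cell probability that the fitted change is positive.

    ``mu_draws`` is (n_draws, n_cells) posterior draws of the fitted mean
    change.  Returns (per-cell probabilities, grand mean %, s.e. %): the
    average probability across cells that a cell increased, with its
    standard error, both in percent.
    """
    mu_draws = np.asarray(mu_draws, float)
    if mu_draws.ndim != 2 or mu_draws.shape[0] < 1:
        raise ValueError("need (n_draws, n_cells) draws")
    p_cell = np.mean(mu_draws > 0, axis=0)
    mean_pct = 100.0 * float(p_cell.mean())
    se_pct = 100.0 * float(p_cell.std(ddof=1) / np.sqrt(p_cell.size))
    return p_cell, mean_pct, se_pct


def _residual_variance(family: str, mu_draw: np.ndarray,
                       hyper: dict[str, float]) -> float:
    """Observation-level residual variance on the link scale."""
    from scipy.special import polygamma

    mu_bar = float(np.mean(mu_draw))
    if family == "gaussian":
        return hyper["sigma"] ** 2
    if family == "poisson":
        return math.log1p(1.0 / mu_bar)
    if family == "negative_binomial":
        return math.log1p(1.0 / mu_bar + 1.0 / hyper["dispersion"])
    if family == "gamma":
        return float(polygamma(1, hyper["dispersion"]))
    if family == "beta":
        return 1.0 / (mu_bar * (1.0 - mu_bar)
                      * (hyper["dispersion"] + 1.0))
    raise ValueError(
        f"no residual-variance convention implemented for {family!r}")


def r2_decomposition(result: PosteriorSummary,
                     max_draws: int = 400) -> tuple[float, float]:
    """Marginal and conditional R² of a fitted model.

    Marginal: variance of the fixed-effect linear predictor over the
    total latent variance (fixed + spatial + iid + distribution-specific
    residual variance on the link scale).  Conditional adds the
    random-effect variances to the numerator.  Averaged over posterior
    draws.
    """
    flat = result.beta_flat()
    total = flat.shape[0]
    step = max(1, total // max_draws)
    idx = np.arange(0, total, step)
    hyper_flat = {k: v.ravel() for k, v in result.hyper_draws.items()}
    r2m, r2c = [], []
    for i in idx:
        lp_fixed = result.X @ flat[i]
        var_fixed = float(np.var(lp_fixed))
        var_sp = (float(np.var(result.gamma_draws[i][result.row_cells]))
                  if result.gamma_draws is not None else 0.0)
        var_iid = (float(np.var(result.nu_draws[i][result.row_cells]))
                   if result.nu_draws is not None else 0.0)
        lp = lp_fixed
        if result.gamma_draws is not None:
            lp = lp + result.gamma_draws[i][result.row_cells]
        if result.nu_draws is not None:
            lp = lp + result.nu_draws[i][result.row_cells]
        link = result.spec.link
        mu = np.exp(lp) if link == "log" else (
            1.0 / (1.0 + np.exp(-lp)) if link == "logit" else lp)
        hyper_i = {k: float(v[i]) for k, v in hyper_flat.items()}
        var_res = _residual_variance(result.spec.family, mu, hyper_i)
        denom = var_fixed + var_sp + var_iid + var_res
        r2m.append(var_fixed / denom)
        r2c.append((var_fixed + var_sp + var_iid) / denom)
    return float(np.mean(r2m)), float(np.mean(r2c))
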