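"""Per-cell biodiversity metrics and between-period change tables.

Three community metrics per grid cell and recording period:

* richness — number of species recorded;
* beta diversity — mean Sørensen dissimilarity between the focal cell and
  its up-to-eight queen neighbours (a decline over time = biotic
  homogenization);
* CTI — community temperature index, the unweighted mean species
  temperature index (STI) of the species present; rises when
  warm-adapted species gain relative occupancy.

Plus LCBD (local contribution to beta diversity, a cell's share of the
total community-matrix variance, summing to 1 across cells), turnover
percentages, the richness-threshold rule that screens cells for CTI
analyses, and the assembly of change tables joining metric differences to
covariate changes and baselines.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .grid import GridDefinition
from .records import presence_matrix, species_sets
from .synthetic import CLIMATE, LAND_USE, CovariateTable

__all__ = ["sorensen", "neighbourhood_beta", "cti", "richness_threshold",
           "lcbd", "turnover", "compute_metrics", "lowest_effort_period",
           "cti_threshold_cells", "build_change_table", "SCALE_PERIODS"]

SCALE_PERIODS = {"long": ("T1", "T3"), "short": ("T2", "T3")}


def sorensen(a: set, b: set) -> float:
    """Sørensen dissimilarity 1 - 2|a∩b| / (|a| + |b|); NaN if both empty."""
    if not a and not b:
        return float("nan")
    return 1.0 - 2.0 * len(a & b) / (len(a) + len(b))


def neighbourhood_beta(cell: str, communities: dict[str, set],
                       grid: GridDefinition) -> tuple[float, int]:
    """Mean Sørensen dissimilarity of a focal cell to its queen neighbours.

    Neighbours with no records are excluded from the mean.  Returns
    (beta, n_neighbours_used); beta is NaN when no neighbour is usable.
    """
    focal = communities.get(cell)
    if not focal:
        raise ValueError(f"cell {cell} has no records in this period")
    vals = [sorensen(focal, communities[nb])
            for nb in grid.neighbours[cell]
            if communities.get(nb)]
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def cti(community: set, sti: dict[str, float]) -> float:
    """Unweighted mean STI over present species with a known STI.

    Species lacking an STI are excluded; NaN when none carries one.
    """
    vals = [sti[s] for s in community
            if s in sti and not math.isnan(sti[s])]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def richness_threshold(max_richness: int, fraction: float = 0.25) -> int:
    """Minimum richness for CTI inclusion: ceil(fraction x max_richness).

    ``max_richness`` is the species count of the richest grid cell in the
    period with the lowest recorder effort; cells below the returned
    cutoff are excluded from CTI analyses.  Ceiling implements the strict
    reading of excluding cells with fewer than 25% of that count.
    """
    if max_richness < 1:
        raise ValueError("max_richness must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return math.ceil(fraction * max_richness)


def lcbd(matrix: pd.DataFrame | np.ndarray,
         transform: str = "hellinger") -> np.ndarray:
    """Local contributions to beta diversity for one period.

    The community matrix (cells x species) is transformed (default
    Hellinger: rows scaled to relative composition, then square-rooted),
    columns are centred, and each cell's LCBD is its share of the total
    sum of squares.  Values are non-negative and sum to 1.  If every
    community is identical the total variance is zero and a uniform 1/n
    is returned with a warning.
    """
    y = np.asarray(matrix, float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 1:
        raise ValueError("need a (>=2 cells) x (>=1 species) matrix")
    if transform == "hellinger":
        rowsum = y.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.sqrt(np.where(rowsum > 0, y / np.where(rowsum > 0,
                                                          rowsum, 1.0), 0.0))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    centred = y - y.mean(axis=0, keepdims=True)
    ss_i = (centred ** 2).sum(axis=1)
    ss_total = ss_i.sum()
    if ss_total <= 0:
        warnings.warn("all communities identical; LCBD set to uniform 1/n")
        return np.full(y.shape[0], 1.0 / y.shape[0])
    return ss_i / ss_total


def turnover(community_t1: set, community_t2: set) -> tuple[float, float]:
    """Percent of the initial community gained and lost by the later one.

    gained = 100 |t2 - t1| / |t1|; lost = 100 |t1 - t2| / |t1|.
    NaN when the initial community is empty.
    """
    if not community_t1:
        return float("nan"), float("nan")
    n1 = len(community_t1)
    gained = 100.0 * len(community_t2 - community_t1) / n1
    lost = 100.0 * len(community_t1 - community_t2) / n1
    return gained, lost


def compute_metrics(records: pd.DataFrame, grid: GridDefinition,
                    sti_table: pd.DataFrame, period: str,
                    lcbd_transform: str = "hellinger") -> pd.DataFrame:
    """Per-cell metric table for one period (recorded cells only).

    ``sti_table`` has columns species_id, sti.  Returns a DataFrame with
    columns cell_id, period, richness, beta, cti, lcbd, n_neighbours_used.
    """
    comms = species_sets(records, period)
    if not comms:
        raise ValueError(f"no records in period {period}")
    cells = sorted(comms)
    sti = dict(zip(sti_table["species_id"], sti_table["sti"]))
    pm = presence_matrix(records, cells, period)
    lcbd_vals = lcbd(pm, transform=lcbd_transform)
    rows = []
    for i, cell in enumerate(cells):
        beta, n_used = neighbourhood_beta(cell, comms, grid)
        rows.append({
            "cell_id": cell, "period": period,
            "richness": len(comms[cell]),
            "beta": beta,
            "cti": cti(comms[cell], sti),
            "lcbd": lcbd_vals[i],
            "n_neighbours_used": n_used,
        })
    return pd.DataFrame(rows)


def lowest_effort_period(effort: pd.DataFrame) -> str:
    """Period whose mean estimated effort across cells is lowest."""
    return effort.groupby("period")["effort"].mean().idxmin()


def cti_threshold_cells(metrics_early: pd.DataFrame,
                        metrics_late: pd.DataFrame,
                        threshold: int) -> list[str]:
    """Cells at or above the richness cutoff in both comparison periods."""
    r_early = metrics_early.set_index("cell_id")["richness"]
    r_late = metrics_late.set_index("cell_id")["richness"]
    shared = r_early.index.intersection(r_late.index)
    ok = shared[(r_early.loc[shared] >= threshold)
                & (r_late.loc[shared] >= threshold)]
    return ok.tolist()


def _standardize(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"column {col.name!r} has zero variance")
    return (col - col.mean()) / sd


def build_change_table(metrics_by_period: dict[str, pd.DataFrame],
                       covariates: CovariateTable,
                       effort: pd.DataFrame,
                       scale: str = "long") -> pd.DataFrame:
    """Join metric changes to covariate changes and baseline conditions.

    For the chosen temporal scale (long: T1->T3, short: T2->T3) the table
    holds, per cell recorded in both periods: the late-minus-early change
    in each metric, each covariate and estimated effort; baseline
    covariates, metrics and effort at the early period; microclimatic
    heterogeneity; and a standardized (mean 0, sd 1) ``z_``-prefixed copy
    of every explanatory column.  Explanatory columns that are entirely
    missing (a land-use category absent from the early map) are kept as
    NaN and skipped by standardization.
    """
    if scale not in SCALE_PERIODS:
        raise ValueError(f"scale must be one of {sorted(SCALE_PERIODS)}")
    early_p, late_p = SCALE_PERIODS[scale]
    early = metrics_by_period[early_p].set_index("cell_id")
    late = metrics_by_period[late_p].set_index("cell_id")
    cells = early.index.intersection(late.index).tolist()
    if not cells:
        raise ValueError("no cells recorded in both periods")

    cov_e = covariates.period(early_p).loc[cells]
    cov_l = covariates.period(late_p).loc[cells]
    eff = effort.pivot(index="cell_id", columns="period", values="effort")
    missing = set(cells) - set(eff.index)
    if missing:
        raise ValueError(f"effort missing for cells: {sorted(missing)[:5]}")
    eff = eff.loc[cells]

    out = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    for m in ("richness", "beta", "cti"):
        out[f"d_{m}"] = late[m] - early[m]
        out[f"baseline_{m}"] = early[m]
    for c in LAND_USE + CLIMATE:
        out[f"d_{c}"] = (cov_l[c] - cov_e[c].fillna(0.0)
                         if cov_e[c].isna().all() else cov_l[c] - cov_e[c])
        out[f"baseline_{c}"] = cov_e[c]
    out["microclim_het"] = cov_l["microclim_het"]
    out["baseline_effort"] = eff[early_p]
    out["d_effort"] = eff[late_p] - eff[early_p]

    explanatory = ([f"d_{c}" for c in LAND_USE + CLIMATE]
                   + [f"baseline_{c}" for c in LAND_USE + CLIMATE]
                   + ["baseline_richness", "baseline_beta", "baseline_cti",
                      "microclim_het", "baseline_effort", "d_effort"])
    for col in explanatory:
        series = out[col]
        if series.isna().all():
            continue  # absent category (e.g. improved grassland at T1)
        valid = series.dropna()
        if valid.std(ddof=0) == 0:
            warnings.warn(f"explanatory column {col!r} is constant; "
                          "no standardized version emitted")
            continue
        z = _standardize(valid)
        out[f"z_{col}"] = z.reindex(out.index)
    out = out.reset_index()
    out.insert(1, "scale", scale)
    return out
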