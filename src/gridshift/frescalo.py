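"""Recorder-effort estimation from presence-only records (Frescalo).

Atlas records carry no measure of how hard recorders searched each cell.
Frescalo estimates that effort from the data themselves: for each focal
cell it forms a neighbourhood of environmentally similar nearby cells,
computes neighbourhood-weighted species frequencies, and asks what power
``alpha`` rescales those frequencies (f' = 1 - (1 - f)^alpha, the
frequency after ``alpha`` repeated searches) so that the weighted mean
frequency phi reaches the value characteristic of a well-recorded cell.
``alpha`` is the sampling-effort multiplier — the number of searches a
cell would need to look well recorded — and effort is its reciprocal
``1 / alpha``.  A separate benchmark-species variant reports the
percentage of common ("benchmark") species a cell actually recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .grid import GridDefinition
from .records import presence_matrix
from .synthetic import LAND_USE, CovariateTable

PHI_DEFAULT = 0.92
N_DIST_DEFAULT = 200
N_SIM_DEFAULT = 100

__all__ = ["NeighbourhoodWeights", "EffortEstimate", "build_neighbourhoods",
           "local_frequencies", "solve_alpha", "estimate_effort",
           "benchmark_detection_effort",
           "PHI_DEFAULT", "N_DIST_DEFAULT", "N_SIM_DEFAULT"]


@dataclass
class NeighbourhoodWeights:
    """Per-focal-cell neighbourhood weights.

    ``weights`` maps focal cell_id -> (array of member cell_ids, array of
    positive weights); the focal cell is always a member of its own
    neighbourhood with the maximal weight.
    """

    weights: dict[str, tuple[np.ndarray, np.ndarray]]
    n_dist: int
    n_sim: int

    @property
    def cell_ids(self) -> list[str]:
        return list(self.weights)

    def matrix(self, cell_ids: list[str]) -> sp.csr_matrix:
        """Sparse (focal x member) weight matrix in ``cell_ids`` order."""
        index = {c: i for i, c in enumerate(cell_ids)}
        rows, cols, vals = [], [], []
        for focal, (ids, w) in self.weights.items():
            fi = index[focal]
            for cid, wi in zip(ids, w):
                rows.append(fi)
                cols.append(index[cid])
                vals.append(wi)
        n = len(cell_ids)
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _taper(rank: np.ndarray, n: int) -> np.ndarray:
    # smooth rank-based taper: rank 1 -> 1, decaying to ~0 at rank n
    return (1.0 - ((rank - 1.0) / n) ** 2) ** 4


def build_neighbourhoods(grid: GridDefinition, covariates: CovariateTable,
                         n_dist: int = N_DIST_DEFAULT,
                         n_sim: int = N_SIM_DEFAULT,
                         reference_period: str | None = None
                         ) -> NeighbourhoodWeights:
    """Distance-then-similarity neighbourhoods with tapered weights.

    For each focal cell: take the ``n_dist`` nearest cells by centroid
    distance (focal first), rank them by land-use similarity to the focal
    cell (1 - Euclidean distance between proportion vectors / sqrt(2)),
    keep the ``n_sim`` most similar, and weight each member by
    distance-taper x similarity-taper on the two ranks.  Ties are broken
    by cell_id order, making the construction deterministic.
    """
    if reference_period is None:
        reference_period = sorted(covariates.data["period"].unique())[0]
    lu = covariates.landuse(reference_period)
    lu = lu.dropna(axis=1, how="all")
    if lu.isna().any().any():
        raise ValueError(
            f"missing land-use data for reference period {reference_period}")
    cell_ids = grid.cell_ids
    lu = lu.loc[cell_ids].to_numpy()
    xy = grid.coordinates()
    ids = np.asarray(cell_ids)
    order_by_id = np.argsort(ids)  # for deterministic tie-breaks

    dist = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    # land-use dissimilarity, bounded by sqrt(2) for probability vectors
    lu_dist = np.linalg.norm(lu[:, None, :] - lu[None, :, :], axis=-1)
    sim = 1.0 - lu_dist / math.sqrt(2.0)

    n = len(cell_ids)
    weights: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    id_rank = np.empty(n)
    id_rank[order_by_id] = np.arange(n)  # lexicographic rank of each cell_id
    for i in range(n):
        d = dist[i].copy()
        d[i] = -1.0  # focal strictly first
        cand = np.lexsort((id_rank, d))[: min(n_dist, n)]
        r_d = np.arange(1, len(cand) + 1)
        s = sim[i, cand].copy()
        s[cand == i] = np.inf  # focal strictly first in similarity too
        sim_order = np.lexsort((id_rank[cand], -s))
        keep = sim_order[: min(n_sim, len(cand))]
        r_s = np.empty(len(cand))
        r_s[sim_order] = np.arange(1, len(cand) + 1)
        w = _taper(r_d[keep], n_dist) * _taper(r_s[keep], n_sim)
        weights[cell_ids[i]] = (ids[cand[keep]], w)
    return NeighbourhoodWeights(weights=weights, n_dist=n_dist, n_sim=n_sim)


def local_frequencies(records: pd.DataFrame, weights: NeighbourhoodWeights,
                      period: str,
                      species_ids: list[str] | None = None) -> pd.DataFrame:
    """Neighbourhood-weighted species frequencies per focal cell.

    f(focal, species) = sum_k w_k [species recorded in k] / sum_k w_k,
    a value in [0, 1]: the fraction of the (weighted) neighbourhood in
    which the species was recorded during ``period``.
    """
    cell_ids = weights.cell_ids
    pm = presence_matrix(records, cell_ids, period, species_ids)
    wmat = weights.matrix(cell_ids)
    totals = np.asarray(wmat.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValueError("empty neighbourhood")
    freq = wmat @ pm.to_numpy(float) / totals[:, None]
    return pd.DataFrame(freq, index=pd.Index(cell_ids, name="cell_id"),
                        columns=pm.columns)


@dataclass
class EffortEstimate:
    """Effort solution for one focal cell and period."""

    alpha: float
    effort: float
    phi_achieved: float
    converged: bool
    cell_id: str | None = None
    period: str | None = None


def _phi(freqs: np.ndarray, alpha: float, weighted: bool) -> float:
    f = 1.0 - np.power(1.0 - freqs, alpha)
    if weighted:
        return float((f ** 2).sum() / f.sum())
    return float(f.mean())


def solve_alpha(freqs, phi_target: float = PHI_DEFAULT,
                weighted: bool = True,
                bracket: tuple[float, float] = (1e-4, 1e4),
                tol: float = 1e-6, max_iter: int = 200) -> EffortEstimate:
    """Find the sampling-effort multiplier alpha for one cell.

    Rescales each local frequency as f' = 1 - (1 - f)^alpha and bisects
    for the alpha at which the frequency-weighted mean phi(alpha) =
    sum f'^2 / sum f' hits ``phi_target`` (the unweighted mean is used
    when ``weighted`` is False).  phi is monotone increasing in alpha, so
    bisection on log(alpha) converges; an unattainable target is reported
    with ``converged=False`` and alpha clamped to the bracket edge.
    """
    freqs = np.asarray(freqs, float)
    freqs = freqs[freqs > 0]
    if freqs.size == 0:
        raise ValueError("need at least one positive local frequency")
    lo, hi = bracket
    phi_lo = _phi(freqs, lo, weighted)
    phi_hi = _phi(freqs, hi, weighted)
    if phi_lo >= phi_target:
        # even a vanishing number of searches overshoots: over-recorded
        # beyond the bracket, or degenerate all-ones frequencies
        return EffortEstimate(lo, 1.0 / lo, phi_lo,
                              abs(phi_lo - phi_target) <= tol)
    if phi_hi <= phi_target:
        return EffortEstimate(hi, 1.0 / hi, phi_hi,
                              abs(phi_hi - phi_target) <= tol)
    llo, lhi = math.log(lo), math.log(hi)
    phi_mid, alpha = phi_lo, lo
    for _ in range(max_iter):
        lmid = 0.5 * (llo + lhi)
        alpha = math.exp(lmid)
        phi_mid = _phi(freqs, alpha, weighted)
        if abs(phi_mid - phi_target) <= tol:
            break
        if phi_mid < phi_target:
            llo = lmid
        else:
            lhi = lmid
    converged = abs(phi_mid - phi_target) <= tol
    return EffortEstimate(alpha, 1.0 / alpha, phi_mid, converged)


def estimate_effort(records: pd.DataFrame, weights: NeighbourhoodWeights,
                    periods=None, phi_target: float = PHI_DEFAULT,
                    weighted: bool = True) -> pd.DataFrame:
    """Frescalo effort for every cell and period.

    Returns a table with columns cell_id, period, alpha, effort,
    phi_achieved, converged.  Cells whose whole neighbourhood lacks any
    record get NaN effort with ``converged=False``.
    """
    if periods is None:
        periods = sorted(records["period"].unique())
    rows = []
    for period in periods:
        freqs = local_frequencies(records, weights, period)
        fmat = freqs.to_numpy()
        for i, cell in enumerate(freqs.index):
            f = fmat[i]
            if not np.any(f > 0):
                rows.append((cell, period, np.nan, np.nan, np.nan, False))
                continue
            est = solve_alpha(f, phi_target=phi_target, weighted=weighted)
            rows.append((cell, period, est.alpha, est.effort,
                         est.phi_achieved, est.converged))
    return pd.DataFrame(rows, columns=["cell_id", "period", "alpha",
                                       "effort", "phi_achieved",
                                       "converged"])


def benchmark_detection_effort(records: pd.DataFrame,
                               weights: NeighbourhoodWeights,
                               benchmark_fraction: float = 0.27,
                               periods=None) -> pd.DataFrame:
    """Percentage of common benchmark species detected in each cell.

    Benchmarks are the top ``benchmark_fraction`` of species by local
    frequency in each focal neighbourhood (at least one).  The effort
    proxy is 100 x (benchmarks recorded in the cell) / (number of
    benchmarks for its neighbourhood) — the recorder-coverage measure
    used for well-surveyed schemes instead of 1/alpha.
    """
    if not 0 < benchmark_fraction <= 1:
        raise ValueError("benchmark_fraction must be in (0, 1]")
    if periods is None:
        periods = sorted(records["period"].unique())
    rows = []
    for period in periods:
        freqs = local_frequencies(records, weights, period)
        species = np.asarray(freqs.columns)
        sub = records[records["period"] == period]
        recorded = {c: set(g["species_id"]) for c, g in
                    sub.groupby("cell_id")}
        for cell in freqs.index:
            f = freqs.loc[cell].to_numpy()
            pos = np.flatnonzero(f > 0)
            if pos.size == 0:
                rows.append((cell, period, np.nan, 0))
                continue
            n_bench = max(1, math.ceil(benchmark_fraction * pos.size))
            order = pos[np.lexsort((species[pos], -f[pos]))][:n_bench]
            bench = set(species[order])
            hit = len(bench & recorded.get(cell, set()))
            rows.append((cell, period, 100.0 * hit / n_bench, n_bench))
    return pd.DataFrame(rows, columns=["cell_id", "period",
                                       "effort_pct", "n_benchmarks"])
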