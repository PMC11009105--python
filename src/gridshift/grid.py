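"""Regular lattice grids with queen (8-neighbour) adjacency.

The analysis operates on a rectangular lattice of square grid cells, the
stand-in for a national atlas grid.  Each cell knows its up-to-eight queen
neighbours; that adjacency drives both the neighbourhood beta-diversity
metric and the intrinsic CAR spatial random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["GridDefinition", "make_grid"]


@dataclass
class GridDefinition:
    """A lattice of grid cells with queen adjacency.

    Attributes
    ----------
    cells : pandas.DataFrame
        One row per cell with columns ``cell_id``, ``row``, ``col``,
        ``x``, ``y`` (planar centroid coordinates, arbitrary units).
    neighbours : dict
        ``cell_id -> list of adjacent cell_ids`` (Chebyshev distance 1).
    """

    cells: pd.DataFrame
    neighbours: dict[str, list[str]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = self.cells["cell_id"].tolist()
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")
        self._index = {c: i for i, c in enumerate(ids)}

    @property
    def cell_ids(self) -> list[str]:
        return self.cells["cell_id"].tolist()

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def index_of(self, cell_id: str) -> int:
        return self._index[cell_id]

    def coordinates(self) -> np.ndarray:
        """(n_cells, 2) array of centroid coordinates."""
        return self.cells[["x", "y"]].to_numpy(float)

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Symmetric binary queen adjacency, ordered as ``cell_ids``."""
        rows, cols = [], []
        for c, nbs in self.neighbours.items():
            i = self._index[c]
            for nb in nbs:
                rows.append(i)
                cols.append(self._index[nb])
        n = self.n_cells
        w = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        return w

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GridDefinition":
        cells = pd.read_csv(path, dtype={"cell_id": str})
        return _from_cells(cells)


def _from_cells(cells: pd.DataFrame) -> GridDefinition:
    """Rebuild queen adjacency from (row, col) indices."""
    pos = {(r, c): cid for cid, r, c in
           zip(cells["cell_id"], cells["row"], cells["col"])}
    neighbours: dict[str, list[str]] = {}
    for cid, r, c in zip(cells["cell_id"], cells["row"], cells["col"]):
        nbs = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = pos.get((r + dr, c + dc))
                if nb is not None:
                    nbs.append(nb)
        neighbours[cid] = nbs
    return GridDefinition(cells=cells, neighbours=neighbours)


def make_grid(n_rows: int, n_cols: int) -> GridDefinition:
    """Build an ``n_rows`` x ``n_cols`` lattice with queen adjacency.

    Cell ids are ``r{row}c{col}``; centroids sit at integer coordinates
    (one unit = one cell width).  Deterministic: no randomness involved.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid dimensions must be >= 2")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols),
                             indexing="ij")
    rows = rows.ravel()
    cols = cols.ravel()
    cells = pd.DataFrame({
        "cell_id": [f"r{r}c{c}" for r, c in zip(rows, cols)],
        "row": rows,
        "col": cols,
        "x": cols.astype(float),
        "y": rows.astype(float),
    })
    return _from_cells(cells)
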