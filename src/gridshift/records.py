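"""Presence-only occurrence records and their matrix views.

An occurrence table is the atlas stand-in: one row per (species, cell,
period) record, presence-only, with no abundance and no direct measure of
how hard anyone looked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PERIODS = ["T1", "T2", "T3"]

__all__ = ["PERIODS", "validate_records", "presence_matrix",
           "species_sets", "read_records", "write_records"]


def validate_records(records: pd.DataFrame,
                     grid=None) -> pd.DataFrame:
    """Check the occurrence-table schema and drop duplicate records.

    Raises if a cell_id is unknown to ``grid`` (when given).  Returns the
    de-duplicated table (one row per species/cell/period).
    """
    required = {"species_id", "cell_id", "period"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if grid is not None:
        known = set(grid.cell_ids)
        bad = set(records["cell_id"]) - known
        if bad:
            raise ValueError(f"records refer to unknown cells: {sorted(bad)[:5]}")
    return records.drop_duplicates(["species_id", "cell_id", "period"])


def presence_matrix(records: pd.DataFrame, cell_ids: list[str],
                    period: str,
                    species_ids: list[str] | None = None) -> pd.DataFrame:
    """Cells x species 0/1 matrix for one period.

    Rows are ordered as ``cell_ids``; cells with no records get all-zero
    rows.  Columns default to the species observed in the period.
    """
    sub = records[records["period"] == period]
    if species_ids is None:
        species_ids = sorted(sub["species_id"].unique())
    mat = pd.DataFrame(0, index=pd.Index(cell_ids, name="cell_id"),
                       columns=species_ids, dtype=np.int8)
    hit = sub[sub["species_id"].isin(species_ids)]
    if len(hit):
        piv = pd.crosstab(hit["cell_id"], hit["species_id"]).clip(upper=1)
        mat.loc[piv.index, piv.columns] = piv.astype(np.int8)
    return mat


def species_sets(records: pd.DataFrame, period: str) -> dict[str, set]:
    """Per-cell species sets for one period (cells with records only)."""
    sub = records[records["period"] == period]
    return {c: set(g["species_id"]) for c, g in sub.groupby("cell_id")}


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
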