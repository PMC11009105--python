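"""Synthetic atlas generator.

Emulates the statistical structure of multi-period national atlas data:
a lattice of grid cells, spatially autocorrelated climate and land-use
covariates with directional trends, a species pool whose occupancy responds
to those covariates (warm-adapted species responding positively to
temperature), and a presence-only recording process with uneven, unknown
recorder effort.  Every quantity the downstream analysis tries to recover
is kept in a :class:`TruthLedger`, so estimators can be tested against
known truth.

The defaults define the desk-scale study conditions: a 20 x 20 grid,
120 species, three recording periods (T1 < T2 < T3), a +0.8 degC warming
trend from T1 to T3, conversion of semi-natural grassland into arable,
improved grassland and urban cover, and recorder effort that is spatially
patchy and rises over time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .grid import GridDefinition, make_grid
from .records import PERIODS, validate_records

LAND_USE = ["arable", "semi_natural_grassland", "improved_grassland",
            "forest", "urban", "water"]
CLIMATE = ["temperature", "precipitation"]
COVARIATES = LAND_USE + CLIMATE + ["microclim_het"]

__all__ = [
    "LAND_USE", "CLIMATE", "COVARIATES",
    "CovariateTable", "SpeciesPool", "TruthLedger", "AtlasDataset",
    "gaussian_field", "simulate_covariates", "make_species_pool",
    "simulate_communities", "make_effort_surface", "simulate_recording",
    "generate_dataset",
]


# ---------------------------------------------------------------------------
# covariates

@dataclass
class CovariateTable:
    """Wide per-cell, per-period covariate table.

    ``data`` has columns ``cell_id``, ``period``, the six land-use
    proportions, ``temperature`` (degC), ``precipitation`` (mm) and
    ``microclim_het`` (unitless >= 0).  ``clamp_events`` counts trend
    applications that had to be clamped into [0, 1].
    """

    data: pd.DataFrame
    clamp_events: int = 0

    def period(self, period: str) -> pd.DataFrame:
        sub = self.data[self.data["period"] == period]
        return sub.set_index("cell_id")

    def landuse(self, period: str) -> pd.DataFrame:
        return self.period(period)[LAND_USE]

    def to_long(self) -> pd.DataFrame:
        return self.data.melt(id_vars=["cell_id", "period"],
                              var_name="variable", value_name="value")

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CovariateTable":
        long = pd.read_csv(path, dtype={"cell_id": str, "period": str})
        wide = long.pivot_table(index=["cell_id", "period"],
                                columns="variable", values="value",
                                dropna=False).reset_index()
        wide.columns.name = None
        return cls(data=wide)


def gaussian_field(grid: GridDefinition, spatial_range: float,
                   rng: np.random.Generator, n_fields: int = 1,
                   nugget: float = 1e-8) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field(s) on the grid.

    Exponential covariance exp(-d / spatial_range) on centroid distance:
    the simplest stationary field with the short-range smoothness that the
    iCAR random effects in the models assume.  Returns shape
    (n_cells, n_fields).
    """
    if spatial_range <= 0:
        raise ValueError("spatial_range must be > 0")
    xy = grid.coordinates()
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    cov = np.exp(-d / spatial_range)
    cov[np.diag_indices_from(cov)] += nugget
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((grid.n_cells, n_fields))
    return chol @ z


DEFAULT_TRENDS = {
    # total shift from T1 to T3, applied in equal per-period steps
    "temperature": 0.8,        # degC; national warming over the study span
    "precipitation": 40.0,     # mm
    # spatially varying anomaly around the trend, per period (sd)
    "temperature_anomaly_sd": 0.25,
    "precipitation_anomaly_sd": 25.0,
    # fraction of each donor category converted per period step; the
    # realised per-cell fraction is jittered so land-use change is not a
    # deterministic function of the baseline composition
    "landuse_transfer": {
        ("semi_natural_grassland", "arable"): 0.06,
        ("semi_natural_grassland", "improved_grassland"): 0.06,
        ("semi_natural_grassland", "urban"): 0.02,
        ("forest", "urban"): 0.01,
    },
    "landuse_transfer_jitter": 0.8,   # relative spread of the fraction
}


def _baseline_landuse(grid: GridDefinition, spatial_range: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Spatially smooth compositional land use via softmax of fields."""
    base_logit = np.log([0.25, 0.30, 0.08, 0.15, 0.10, 0.12])
    fields = gaussian_field(grid, spatial_range, rng, n_fields=len(LAND_USE))
    logits = base_logit[None, :] + 0.8 * fields
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def simulate_covariates(grid: GridDefinition, n_periods: int = 3,
                        trend_params: dict | None = None,
                        spatial_range: float = 5.0,
                        seed: int | np.random.SeedSequence = 0,
                        mask_improved_t1: bool = False) -> CovariateTable:
    """Simulate spatially autocorrelated covariates with directional trends.

    Temperature and precipitation are Gaussian-field draws plus a linear
    trend across periods.  Land use starts from a smooth composition and
    evolves by transferring mass between categories (semi-natural grassland
    losing cover to arable, improved grassland and urban by default),
    renormalising after each step.  Microclimatic heterogeneity is a static
    positive surface (modern topography changes little over the study span).

    ``mask_improved_t1`` blanks the improved-grassland proportion in T1
    (after spreading its mass over the other categories), mirroring a
    historical land-cover map that lacked the category.
    """
    if n_periods < 2:
        raise ValueError("need at least 2 periods")
    trends = dict(DEFAULT_TRENDS)
    if trend_params:
        trends.update(trend_params)
    rng = np.random.default_rng(seed)
    periods = PERIODS[:n_periods]

    temp_field = gaussian_field(grid, spatial_range, rng)[:, 0]
    prec_field = gaussian_field(grid, spatial_range, rng)[:, 0]
    micro = np.abs(gaussian_field(grid, spatial_range / 2, rng)[:, 0]) * 0.5 + 0.1
    temp0 = 9.0 + 1.5 * temp_field
    prec0 = 900.0 + 120.0 * prec_field

    lu = _baseline_landuse(grid, spatial_range, rng)
    clamp_events = 0
    frames = []
    jitter = trends["landuse_transfer_jitter"]
    for t, period in enumerate(periods):
        step = t / (n_periods - 1)
        temp = temp0 + trends["temperature"] * step
        prec = prec0 + trends["precipitation"] * step
        if t > 0:
            # zero-mean spatial anomalies keep the grand-mean trend exact
            ta = gaussian_field(grid, spatial_range, rng)[:, 0]
            pa = gaussian_field(grid, spatial_range, rng)[:, 0]
            temp = temp + trends["temperature_anomaly_sd"] * (ta - ta.mean())
            prec = prec + trends["precipitation_anomaly_sd"] * (pa - pa.mean())
            lu = lu.copy()
            for (src, dst), frac in trends["landuse_transfer"].items():
                i, j = LAND_USE.index(src), LAND_USE.index(dst)
                mult = np.clip(
                    1.0 + jitter * gaussian_field(grid, spatial_range,
                                                  rng)[:, 0],
                    0.0, 2.0)
                moved = lu[:, i] * frac * mult
                lu[:, i] -= moved
                lu[:, j] += moved
            bad = (lu < 0) | (lu > 1)
            if bad.any():
                clamp_events += int(bad.sum())
                lu = np.clip(lu, 0.0, 1.0)
            lu = lu / lu.sum(axis=1, keepdims=True)
        frame = pd.DataFrame(lu, columns=LAND_USE)
        frame.insert(0, "period", period)
        frame.insert(0, "cell_id", grid.cell_ids)
        frame["temperature"] = temp
        frame["precipitation"] = prec
        frame["microclim_het"] = micro
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    if clamp_events:
        warnings.warn(f"{clamp_events} land-use proportions clamped to [0,1]")
    if mask_improved_t1:
        t1 = data["period"] == periods[0]
        spread = data.loc[t1, "improved_grassland"].to_numpy()
        others = [c for c in LAND_USE if c != "improved_grassland"]
        sub = data.loc[t1, others].to_numpy()
        sub = sub + spread[:, None] * sub / sub.sum(axis=1, keepdims=True)
        data.loc[t1, others] = sub
        data.loc[t1, "improved_grassland"] = np.nan
    return CovariateTable(data=data, clamp_events=clamp_events)


# ---------------------------------------------------------------------------
# species pool and communities

RESPONSE_COVARIATES = ["temperature", "precipitation", "arable",
                       "semi_natural_grassland", "urban"]


@dataclass
class SpeciesPool:
    """Species attributes: STI, commonness and occupancy-scale slopes.

    ``table`` columns: ``species_id``, ``sti`` (degC; NaN when unknown),
    ``commonness`` (baseline occupancy propensity in (0,1)) and one
    ``slope_<covariate>`` column per responding covariate.
    """

    table: pd.DataFrame

    @property
    def species_ids(self) -> list[str]:
        return self.table["species_id"].tolist()

    def sti_table(self) -> pd.DataFrame:
        return self.table[["species_id", "sti"]].copy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpeciesPool":
        return cls(pd.read_csv(path, dtype={"species_id": str}))


def make_species_pool(n_species: int = 120,
                      seed: int | np.random.SeedSequence = 0,
                      sti_mean: float = 9.0, sti_sd: float = 2.0,
                      missing_sti_fraction: float = 0.05,
                      temperature_coupling: float = 0.6,
                      slope_sd: float = 0.25) -> SpeciesPool:
    """Draw a species pool.

    ``temperature_coupling`` ties the temperature slope to the (centred,
    scaled) STI so that warm-adapted species respond positively to warming
    -- the construction that makes the community temperature index rise
    under a warming trend.  A ``missing_sti_fraction`` of species get their
    STI blanked, mirroring real STI tables that do not cover every species.
    """
    if n_species < 1:
        raise ValueError("pool must be non-empty")
    rng = np.random.default_rng(seed)
    sti = rng.normal(sti_mean, sti_sd, n_species)
    commonness = np.clip(rng.beta(2.0, 2.5, n_species), 0.02, 0.98)
    z_sti = (sti - sti_mean) / sti_sd
    table = pd.DataFrame({
        "species_id": [f"sp{i:03d}" for i in range(n_species)],
        "sti": sti,
        "commonness": commonness,
    })
    for cov in RESPONSE_COVARIATES:
        slopes = rng.normal(0.0, slope_sd, n_species)
        if cov == "temperature":
            slopes = slopes + temperature_coupling * z_sti
        table[f"slope_{cov}"] = slopes
    if missing_sti_fraction > 0:
        n_missing = int(round(missing_sti_fraction * n_species))
        drop = rng.choice(n_species, size=n_missing, replace=False)
        table.loc[drop, "sti"] = np.nan
    return SpeciesPool(table=table)


@dataclass
class TruthLedger:
    """Ground truth behind one synthetic dataset.

    ``occupancy`` is (n_periods, n_cells, n_species) of 0/1; the
    standardisation constants used inside the occupancy model are kept so
    the generating process is fully reproducible from the ledger alone.
    """

    occupancy: np.ndarray
    cell_ids: list[str]
    species_ids: list[str]
    periods: list[str]
    pool: SpeciesPool
    params: dict
    seed: int | None
    effort: pd.DataFrame | None = None  # cell_id, period, effort

    def occupancy_frame(self, period: str) -> pd.DataFrame:
        t = self.periods.index(period)
        return pd.DataFrame(self.occupancy[t], index=self.cell_ids,
                            columns=self.species_ids)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for p in self.periods:
            self.occupancy_frame(p).to_csv(path / f"occupancy_{p}.csv")
        self.pool.to_csv(path / "species_pool.csv")
        if self.effort is not None:
            self.effort.to_csv(path / "true_effort.csv", index=False)
        manifest = {"seed": self.seed, "periods": self.periods,
                    "params": self.params}
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def simulate_communities(grid: GridDefinition, covariates: CovariateTable,
                         pool: SpeciesPool, spatial_sd: float = 0.5,
                         seed: int | np.random.SeedSequence = 0,
                         spatial_range: float = 5.0) -> TruthLedger:
    """Draw true occupancy for every species, cell and period.

    Occupancy probability is inverse-logit(logit(commonness) + slopes x
    standardised covariates + a per-species spatial field with sd
    ``spatial_sd``): linear covariate effects plus a spatially structured
    residual, the data-generating form the attribution models assume.
    Covariates are standardised against their first-period mean and sd so
    the directional trends shift occupancy over time.
    """
    if len(pool.table) == 0:
        raise ValueError("pool must be non-empty")
    rng = np.random.default_rng(seed)
    periods = sorted(covariates.data["period"].unique(),
                     key=PERIODS.index)
    cell_ids = grid.cell_ids
    n_cells, n_species = len(cell_ids), len(pool.table)

    ref = covariates.period(periods[0]).loc[cell_ids]
    mu0 = {c: np.nanmean(ref[c]) for c in RESPONSE_COVARIATES}
    sd0 = {c: max(np.nanstd(ref[c]), 1e-12) for c in RESPONSE_COVARIATES}

    slopes = pool.table[[f"slope_{c}" for c in RESPONSE_COVARIATES]
                        ].to_numpy()                       # species x cov
    intercept = logit(pool.table["commonness"].to_numpy())  # species
    if spatial_sd > 0:
        fields = spatial_sd * gaussian_field(grid, spatial_range, rng,
                                             n_fields=n_species)
    else:
        fields = np.zeros((n_cells, n_species))

    occupancy = np.empty((len(periods), n_cells, n_species), dtype=np.int8)
    for t, period in enumerate(periods):
        cov = covariates.period(period).loc[cell_ids]
        z = np.column_stack([
            (np.nan_to_num(cov[c].to_numpy(), nan=mu0[c]) - mu0[c]) / sd0[c]
            for c in RESPONSE_COVARIATES])                 # cells x cov
        lp = intercept[None, :] + z @ slopes.T + fields
        p = expit(lp)
        occupancy[t] = (rng.random((n_cells, n_species)) < p).astype(np.int8)

    params = {"spatial_sd": spatial_sd, "spatial_range": spatial_range,
              "standardisation": {"mean": mu0, "sd": sd0}}
    return TruthLedger(occupancy=occupancy, cell_ids=cell_ids,
                       species_ids=pool.species_ids, periods=list(periods),
                       pool=pool, params=params,
                       seed=seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# recording

def make_effort_surface(grid: GridDefinition, n_periods: int = 3,
                        period_means: tuple = (0.5, 0.65, 0.8),
                        spatial_range: float = 4.0, sd: float = 0.8,
                        seed: int | np.random.SeedSequence = 0
                        ) -> pd.DataFrame:
    """Spatially patchy recorder effort in (0, 1), rising over periods.

    Effort is inverse-logit(logit(period mean) + spatial field); the field
    is redrawn each period so recording hot-spots move around, as recording
    schemes' coverage does between atlas projects.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(n_periods):
        f = gaussian_field(grid, spatial_range, rng)[:, 0]
        eff = expit(logit(period_means[t]) + sd * f)
        frames.append(pd.DataFrame({"cell_id": grid.cell_ids,
                                    "period": PERIODS[t],
                                    "effort": eff}))
    return pd.concat(frames, ignore_index=True)


def simulate_recording(truth: TruthLedger, effort: pd.DataFrame,
                       seed: int | np.random.SeedSequence = 0,
                       exposure_scale: float = 4.0) -> pd.DataFrame:
    """Thin true occupancy into presence-only records.

    A truly present species j is recorded in a cell with probability
    ``1 - (1 - effort)^(exposure_scale * commonness_j)``: effort acts like
    the success probability of repeated searches, with commoner species
    exposed to more of them.  Effort 1 records every present species;
    effort must lie in (0, 1].
    """
    eff = effort.pivot(index="cell_id", columns="period", values="effort")
    eff = eff.loc[truth.cell_ids, truth.periods].to_numpy()
    if np.any(eff <= 0) or np.any(eff > 1):
        raise ValueError("effort values must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    commonness = truth.pool.table["commonness"].to_numpy()
    exponent = exposure_scale * commonness                     # species
    rows = []
    for t, period in enumerate(truth.periods):
        p_detect = 1.0 - np.power(1.0 - eff[:, t][:, None],
                                  exponent[None, :])
        detected = truth.occupancy[t].astype(bool) & (
            rng.random(p_detect.shape) < p_detect)
        ci, si = np.nonzero(detected)
        rows.append(pd.DataFrame({
            "species_id": np.asarray(truth.species_ids)[si],
            "cell_id": np.asarray(truth.cell_ids)[ci],
            "period": period,
        }))
    records = pd.concat(rows, ignore_index=True)
    return validate_records(records)


# ---------------------------------------------------------------------------
# one-call bundle

@dataclass
class AtlasDataset:
    """Everything one synthetic study needs, generated from one seed."""

    grid: GridDefinition
    covariates: CovariateTable
    pool: SpeciesPool
    truth: TruthLedger
    effort: pd.DataFrame
    records: pd.DataFrame
    config: dict = field(default_factory=dict)


DEFAULT_CONFIG = {
    "n_rows": 20, "n_cols": 20, "n_species": 120, "n_periods": 3,
    "spatial_range": 5.0, "spatial_sd": 0.5,
    "trend_params": None, "mask_improved_t1": False,
    "effort_period_means": (0.5, 0.65, 0.8), "effort_sd": 0.8,
    "exposure_scale": 4.0,
    "missing_sti_fraction": 0.05, "temperature_coupling": 0.6,
    "slope_sd": 0.25,
}


def generate_dataset(seed: int = 0, **overrides) -> AtlasDataset:
    """Generate a full synthetic atlas dataset at desk scale.

    All randomness derives from ``seed`` via independent child streams, so
    one integer reproduces the whole dataset bit for bit.
    """
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(overrides) - set(cfg)
    if unknown:
        raise TypeError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(overrides)
    ss = np.random.SeedSequence(seed).spawn(4)
    grid = make_grid(cfg["n_rows"], cfg["n_cols"])
    covariates = simulate_covariates(
        grid, n_periods=cfg["n_periods"], trend_params=cfg["trend_params"],
        spatial_range=cfg["spatial_range"], seed=ss[0],
        mask_improved_t1=cfg["mask_improved_t1"])
    pool = make_species_pool(
        cfg["n_species"], seed=ss[1],
        missing_sti_fraction=cfg["missing_sti_fraction"],
        temperature_coupling=cfg["temperature_coupling"],
        slope_sd=cfg["slope_sd"])
    truth = simulate_communities(
        grid, covariates, pool, spatial_sd=cfg["spatial_sd"], seed=ss[2],
        spatial_range=cfg["spatial_range"])
    truth.seed = seed
    effort = make_effort_surface(
        grid, n_periods=cfg["n_periods"],
        period_means=cfg["effort_period_means"], sd=cfg["effort_sd"],
        seed=ss[3])
    truth.effort = effort
    records = simulate_recording(truth, effort, seed=np.random.SeedSequence(
        entropy=seed, spawn_key=(99,)),
        exposure_scale=cfg["exposure_scale"])
    return AtlasDataset(grid=grid, covariates=covariates, pool=pool,
                        truth=truth, effort=effort, records=records,
                        config=cfg)
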