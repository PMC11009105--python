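import numpy as np
import pandas as pd
import pytest

from gridshift.grid import make_grid
from gridshift.records import validate_records
from gridshift import synthetic as syn


def test_covariates_deterministic_under_seed(grid5):
    a = syn.simulate_covariates(grid5, seed=7)
    b = syn.simulate_covariates(grid5, seed=7)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_landuse_proportions_sum_to_one(small_dataset):
    sums = small_dataset.covariates.data[syn.LAND_USE].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_temperature_trend_recovered_at_scale():
    # >= 1000 cells; anomalies are centred, so the grand-mean shift should
    # match the configured +0.8 degC within a hair
    g = make_grid(32, 32)
    cov = syn.simulate_covariates(g, seed=3)
    t1 = cov.period("T1")["temperature"].mean()
    t3 = cov.period("T3")["temperature"].mean()
    assert t3 - t1 == pytest.approx(0.8, abs=0.05)


def test_zero_slopes_and_half_commonness_give_half_occupancy(grid5):
    cov = syn.simulate_covariates(grid5, seed=0)
    pool = syn.make_species_pool(60, seed=0, slope_sd=0.0,
                                 temperature_coupling=0.0,
                                 missing_sti_fraction=0.0)
    pool.table["commonness"] = 0.5
    truth = syn.simulate_communities(grid5, cov, pool, spatial_sd=0.0,
                                     seed=5)
    occ = truth.occupancy.mean()
    # 25 cells x 60 species x 3 periods Bernoulli(0.5)
    assert abs(occ - 0.5) < 3 * 0.5 / np.sqrt(truth.occupancy.size)


def test_true_cti_rises_under_warming():
    g = make_grid(8, 8)
    diffs = []
    for seed in range(5):
        cov = syn.simulate_covariates(g, seed=seed)
        pool = syn.make_species_pool(80, seed=seed, slope_sd=0.05,
                                     temperature_coupling=1.0,
                                     missing_sti_fraction=0.0)
        truth = syn.simulate_communities(g, cov, pool, spatial_sd=0.1,
                                         seed=seed + 100)
        sti = pool.table["sti"].to_numpy()

        def true_cti(t):
            occ = truth.occupancy[t].astype(bool)
            return np.mean([sti[row].mean() for row in occ if row.any()])

        diffs.append(true_cti(2) - true_cti(0))
    assert np.mean(diffs) > 0


def test_occupancy_bitwise_reproducible(grid5):
    cov = syn.simulate_covariates(grid5, seed=2)
    pool = syn.make_species_pool(30, seed=2)
    a = syn.simulate_communities(grid5, cov, pool, seed=9)
    b = syn.simulate_communities(grid5, cov, pool, seed=9)
    assert np.array_equal(a.occupancy, b.occupancy)


def test_full_effort_records_equal_truth(grid5):
    cov = syn.simulate_covariates(grid5, seed=2)
    pool = syn.make_species_pool(30, seed=2)
    truth = syn.simulate_communities(grid5, cov, pool, seed=9)
    effort = pd.DataFrame([
        {"cell_id": c, "period": p, "effort": 1.0}
        for c in grid5.cell_ids for p in truth.periods])
    records = syn.simulate_recording(truth, effort, seed=1)
    for t, period in enumerate(truth.periods):
        sub = records[records["period"] == period]
        assert len(sub) == truth.occupancy[t].sum()


def test_zero_effort_rejected(grid5):
    cov = syn.simulate_covariates(grid5, seed=2)
    pool = syn.make_species_pool(10, seed=2)
    truth = syn.simulate_communities(grid5, cov, pool, seed=9)
    effort = pd.DataFrame([
        {"cell_id": c, "period": p, "effort": 0.0}
        for c in grid5.cell_ids for p in truth.periods])
    with pytest.raises(ValueError, match="effort"):
        syn.simulate_recording(truth, effort, seed=1)


def test_halving_effort_lowers_expected_recorded_richness(grid5):
    cov = syn.simulate_covariates(grid5, seed=2)
    pool = syn.make_species_pool(40, seed=2, missing_sti_fraction=0.0)
    truth = syn.simulate_communities(grid5, cov, pool, seed=9)
    target = grid5.cell_ids[7]
    base = pd.DataFrame([
        {"cell_id": c, "period": p, "effort": 0.6}
        for c in grid5.cell_ids for p in truth.periods])
    halved = base.copy()
    halved.loc[halved["cell_id"] == target, "effort"] = 0.3
    rich_full, rich_half = [], []
    for rep in range(500):
        r1 = syn.simulate_recording(truth, base, seed=rep)
        r2 = syn.simulate_recording(truth, halved, seed=rep)
        rich_full.append(((r1["cell_id"] == target)
                          & (r1["period"] == "T1")).sum())
        rich_half.append(((r2["cell_id"] == target)
                          & (r2["period"] == "T1")).sum())
    assert np.mean(rich_half) < np.mean(rich_full)


def test_generated_dataset_satisfies_downstream_schema(small_dataset):
    ds = small_dataset
    validate_records(ds.records, ds.grid)
    assert set(ds.records["period"]) <= {"T1", "T2", "T3"}
    assert not ds.covariates.data[syn.CLIMATE + ["microclim_het"]
                                  ].isna().any().any()
    eff = ds.effort["effort"]
    assert ((eff > 0) & (eff <= 1)).all()
    # dataset regeneration from the same seed is byte-identical
    again = syn.generate_dataset(seed=42, n_rows=8, n_cols=8, n_species=40)
    pd.testing.assert_frame_equal(ds.records, again.records)
    pd.testing.assert_frame_equal(ds.covariates.data, again.covariates.data)


def test_masked_improved_grassland_still_sums_to_one(grid5):
    cov = syn.simulate_covariates(grid5, seed=4, mask_improved_t1=True)
    t1 = cov.period("T1")
    assert t1["improved_grassland"].isna().all()
    others = [c for c in syn.LAND_USE if c != "improved_grassland"]
    assert np.allclose(t1[others].sum(axis=1), 1.0, atol=1e-9)


def test_truth_ledger_round_trip(tmp_path, small_dataset):
    small_dataset.truth.to_dir(tmp_path / "truth")
    occ = pd.read_csv(tmp_path / "truth" / "occupancy_T1.csv",
                      index_col=0)
    assert np.array_equal(occ.to_numpy(),
                          small_dataset.truth.occupancy[0])
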