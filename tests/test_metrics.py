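import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gridshift.grid import make_grid
from gridshift import metrics as cm
from gridshift import synthetic as syn
from gridshift.records import species_sets

species_sets_strategy = st.sets(
    st.sampled_from([f"s{i}" for i in range(12)]), max_size=12)


def test_sorensen_identity_and_disjoint():
    assert cm.sorensen({"a", "b"}, {"a", "b"}) == 0.0
    assert cm.sorensen({"a"}, {"b", "c"}) == 1.0
    assert cm.sorensen({"s1", "s2"}, {"s2", "s3"}) == pytest.approx(0.5)
    assert np.isnan(cm.sorensen(set(), set()))


@settings(deadline=None, max_examples=200)
@given(a=species_sets_strategy, b=species_sets_strategy)
def test_sorensen_symmetric_and_bounded(a, b):
    if not a and not b:
        return
    d = cm.sorensen(a, b)
    assert d == cm.sorensen(b, a)
    assert 0.0 <= d <= 1.0


@settings(deadline=None, max_examples=200)
@given(a=species_sets_strategy, b=species_sets_strategy)
def test_shared_species_never_increases_dissimilarity(a, b):
    if not a and not b:
        return
    before = cm.sorensen(a, b)
    extra = "shared_new"
    after = cm.sorensen(a | {extra}, b | {extra})
    assert after <= before + 1e-12


def test_neighbourhood_beta_extremes_and_mean():
    g = make_grid(3, 3)
    same = {c: {"a", "b"} for c in g.cell_ids}
    beta, n = cm.neighbourhood_beta("r1c1", same, g)
    assert beta == 0.0 and n == 8
    disjoint = {c: {c} for c in g.cell_ids}
    beta, n = cm.neighbourhood_beta("r1c1", disjoint, g)
    assert beta == 1.0 and n == 8
    # two usable neighbours with dissimilarities 0.2 and 0.6
    comms = {"r0c0": {"a", "b", "c", "d", "e"},
             "r0c1": {"a", "b", "c", "d", "f"},     # sorensen 0.2
             "r1c1": {"a", "b", "x", "y", "z"}}     # sorensen 0.6
    beta, n = cm.neighbourhood_beta("r0c0", comms, g)
    assert n == 2
    assert beta == pytest.approx(0.4)


def test_neighbourhood_beta_needs_records():
    g = make_grid(3, 3)
    with pytest.raises(ValueError):
        cm.neighbourhood_beta("r0c0", {}, g)
    beta, n = cm.neighbourhood_beta("r0c0", {"r0c0": {"a"}}, g)
    assert np.isnan(beta) and n == 0


def test_cti_mean_and_missing_sti():
    sti = {"a": 9.3, "b": 8.0, "c": 10.0, "d": float("nan")}
    assert cm.cti({"a"}, sti) == pytest.approx(9.3)
    assert cm.cti({"b", "c"}, sti) == pytest.approx(9.0)
    community = {"a", "b", "c", "d", "e"}   # d lacks STI, e unknown
    known = [9.3, 8.0, 10.0]
    assert cm.cti(community, sti) == pytest.approx(np.mean(known))
    assert np.isnan(cm.cti({"d", "e"}, sti))


def test_cti_mean_fixed_point():
    sti = {"a": 8.0, "b": 10.0}
    current = cm.cti({"a", "b"}, sti)
    sti["new"] = current
    assert cm.cti({"a", "b", "new"}, sti) == pytest.approx(current)


@pytest.mark.parametrize("max_richness,expected",
                         [(39, 10), (854, 214), (100, 25), (1, 1)])
def test_richness_threshold_values(max_richness, expected):
    assert cm.richness_threshold(max_richness, 0.25) == expected


def test_richness_threshold_validation():
    with pytest.raises(ValueError):
        cm.richness_threshold(0, 0.25)
    with pytest.raises(ValueError):
        cm.richness_threshold(10, 0.0)
    with pytest.raises(ValueError):
        cm.richness_threshold(10, 1.5)


def lcbd_brute_force(mat):
    """Independent oracle: explicit Hellinger + double-loop sums of squares."""
    y = np.array(mat, float)
    h = np.zeros_like(y)
    for i in range(y.shape[0]):
        s = y[i].sum()
        for j in range(y.shape[1]):
            h[i, j] = np.sqrt(y[i, j] / s) if s > 0 else 0.0
    means = h.mean(axis=0)
    ss = np.zeros(y.shape[0])
    for i in range(y.shape[0]):
        for j in range(y.shape[1]):
            ss[i] += (h[i, j] - means[j]) ** 2
    return ss / ss.sum()


def test_lcbd_toy_matrix_matches_brute_force():
    mat = [[1, 0], [1, 1], [0, 1]]
    np.testing.assert_allclose(cm.lcbd(mat), lcbd_brute_force(mat),
                               atol=1e-12)


def test_lcbd_sums_to_one_and_uniform_when_identical(rng):
    mat = rng.integers(0, 2, size=(12, 20))
    mat[:, 0] = 1  # avoid empty rows
    vals = cm.lcbd(mat)
    assert vals.sum() == pytest.approx(1.0, abs=1e-9)
    with pytest.warns(UserWarning, match="identical"):
        uniform = cm.lcbd(np.ones((5, 4)))
    np.testing.assert_allclose(uniform, 0.2)


def test_lcbd_invariant_to_species_order(rng):
    mat = rng.integers(0, 2, size=(10, 15)).astype(float)
    mat[:, 0] = 1
    perm = rng.permutation(15)
    np.testing.assert_allclose(cm.lcbd(mat), cm.lcbd(mat[:, perm]),
                               atol=1e-12)


def test_turnover_cases():
    assert cm.turnover({"a", "b"}, {"a", "b"}) == (0.0, 0.0)
    assert cm.turnover({"a", "b"}, set()) == (0.0, 100.0)
    gained, lost = cm.turnover({"a", "b", "c", "d"}, {"a", "b", "e"})
    assert gained == pytest.approx(25.0)
    assert lost == pytest.approx(50.0)
    assert all(np.isnan(v) for v in cm.turnover(set(), {"a"}))


def test_compute_metrics_richness_ignores_duplicate_records(small_dataset):
    ds = small_dataset
    sti = ds.pool.sti_table()
    base = cm.compute_metrics(ds.records, ds.grid, sti, "T1")
    doubled = pd.concat([ds.records, ds.records], ignore_index=True)
    again = cm.compute_metrics(doubled, ds.grid, sti, "T1")
    pd.testing.assert_frame_equal(base, again)
    comms = species_sets(ds.records, "T1")
    row = base.set_index("cell_id")
    for cell in list(comms)[:5]:
        assert row.loc[cell, "richness"] == len(comms[cell])


def test_change_table_identical_periods_give_zero_change(small_dataset):
    ds = small_dataset
    sti = ds.pool.sti_table()
    m1 = cm.compute_metrics(ds.records, ds.grid, sti, "T1")
    m3 = m1.copy()
    m3["period"] = "T3"
    eff = pd.concat([
        pd.DataFrame({"cell_id": ds.grid.cell_ids, "period": p,
                      "effort": 0.5})
        for p in ("T1", "T3")], ignore_index=True)
    table = cm.build_change_table({"T1": m1, "T3": m3},
                                  ds.covariates, eff, scale="long")
    assert np.allclose(table["d_richness"], 0)
    assert np.allclose(table["d_beta"].dropna(), 0)
    zcols = [c for c in table.columns if c.startswith("z_")]
    for c in zcols:
        vals = table[c].dropna()
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_change_table_matches_hand_built_oracle():
    g = make_grid(2, 3)
    cells = g.cell_ids[:5]
    rng = np.random.default_rng(0)

    def mk(period, rich):
        return pd.DataFrame({
            "cell_id": cells, "period": period, "richness": rich,
            "beta": rng.random(5) * 0.5 + 0.2,
            "cti": rng.random(5) + 9.0,
            "lcbd": np.full(5, 0.2), "n_neighbours_used": 3,
        })

    m1 = mk("T1", [10, 12, 8, 20, 15])
    m3 = mk("T3", [11, 10, 9, 25, 15])
    cov = syn.simulate_covariates(g, seed=1)
    eff = pd.concat([
        pd.DataFrame({"cell_id": g.cell_ids, "period": p,
                      "effort": rng.random(6) * 0.5 + 0.4})
        for p in ("T1", "T2", "T3")], ignore_index=True)
    table = cm.build_change_table({"T1": m1, "T3": m3}, cov, eff,
                                  scale="long").set_index("cell_id")
    effw = eff.pivot(index="cell_id", columns="period", values="effort")
    cov1 = cov.period("T1")
    cov3 = cov.period("T3")
    for i, cell in enumerate(cells):
        assert table.loc[cell, "d_richness"] == \
            m3["richness"][i] - m1["richness"][i]
        assert table.loc[cell, "baseline_richness"] == m1["richness"][i]
        assert table.loc[cell, "d_temperature"] == pytest.approx(
            cov3.loc[cell, "temperature"] - cov1.loc[cell, "temperature"])
        assert table.loc[cell, "baseline_arable"] == pytest.approx(
            cov1.loc[cell, "arable"])
        assert table.loc[cell, "d_effort"] == pytest.approx(
            effw.loc[cell, "T3"] - effw.loc[cell, "T1"])


def test_cti_threshold_cells_filters_both_periods():
    m1 = pd.DataFrame({"cell_id": ["a", "b", "c"], "period": "T1",
                       "richness": [5, 20, 30]})
    m3 = pd.DataFrame({"cell_id": ["a", "b", "c"], "period": "T3",
                       "richness": [25, 8, 31]})
    keep = cm.cti_threshold_cells(m1, m3, threshold=10)
    assert keep == ["c"]
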