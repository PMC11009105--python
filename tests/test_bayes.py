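import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gridshift import bayes
from gridshift.grid import make_grid
from gridshift.synthetic import gaussian_field

FAST = bayes.SamplerConfig(chains=2, warmup=300, draws=300)


def test_icar_diagonal_is_neighbour_count():
    q = bayes.build_icar(make_grid(3, 3))
    np.testing.assert_allclose(q.Q.diagonal(),
                               [3, 5, 3, 5, 8, 5, 3, 5, 3])
    # Q annihilates constants on a connected grid
    ones = np.ones(9)
    np.testing.assert_allclose(q.Q @ ones, 0.0, atol=1e-12)


def test_icar_quadratic_form_equals_edge_sum(rng):
    g = make_grid(6, 5)
    q = bayes.build_icar(g)
    u = rng.standard_normal(g.n_cells)
    edge_sum = 0.0
    for c, nbs in g.neighbours.items():
        i = g.index_of(c)
        for nb in nbs:
            j = g.index_of(nb)
            if i < j:
                edge_sum += (u[i] - u[j]) ** 2
    assert u @ (q.Q @ u) == pytest.approx(edge_sum)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        bayes.ModelSpec("weibull", "y", [])
    with pytest.raises(ValueError):
        bayes.ModelSpec("poisson", "y", [], spatial_effect="car2")
    assert bayes.ModelSpec("beta", "y", []).link == "logit"


def test_response_validation_and_beta_nudge():
    with pytest.raises(ValueError):
        bayes.fit(bayes.ModelSpec("poisson", "y", [], sampler=FAST),
                  pd.DataFrame({"y": [1.5, 2.0]}))
    with pytest.raises(ValueError):
        bayes.fit(bayes.ModelSpec("gamma", "y", [], sampler=FAST),
                  pd.DataFrame({"y": [0.0, 1.0]}))
    with pytest.raises(ValueError, match="missing"):
        bayes.fit(bayes.ModelSpec("gaussian", "y", [], sampler=FAST),
                  pd.DataFrame({"y": [np.nan, 1.0]}))
    y = np.concatenate([[0.0, 1.0], np.linspace(0.2, 0.8, 48)])
    with pytest.warns(UserWarning, match="nudged"):
        res = bayes.fit(bayes.ModelSpec("beta", "y", [], sampler=FAST),
                        pd.DataFrame({"y": y}), seed=0)
    assert res.coefficients["mean"].notna().all()


def test_gaussian_nonspatial_matches_ols(rng):
    n = 200
    x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
    y = 1.0 + 0.5 * x1 - 0.8 * x2 + rng.normal(0, 0.5, n)
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    res = bayes.fit(bayes.ModelSpec("gaussian", "y", ["x1", "x2"],
                                    sampler=FAST), df, seed=1)
    ols = sm.OLS(y, res.X).fit()
    np.testing.assert_allclose(res.coefficients["mean"], ols.params,
                               atol=0.05)
    r2m, r2c = bayes.r2_decomposition(res)
    assert r2m == pytest.approx(r2c)
    assert r2m == pytest.approx(ols.rsquared, abs=0.05)


def test_gaussian_conjugate_posterior_closed_form(rng):
    # intercept-only Gaussian: posterior of the mean is ~ N(ybar, sigma^2/n)
    y = rng.normal(3.0, 1.0, 400)
    res = bayes.fit(bayes.ModelSpec("gaussian", "y", [], sampler=FAST),
                    pd.DataFrame({"y": y}), seed=2)
    c = res.coefficient("intercept")
    assert c["mean"] == pytest.approx(y.mean(), abs=3 * 1.0 / 20)
    assert c["sd"] == pytest.approx(y.std() / 20, rel=0.25)


def test_poisson_intercept_only_matches_mle(rng):
    y = rng.poisson(6.0, 400)
    res = bayes.fit(bayes.ModelSpec("poisson", "y", [], sampler=FAST),
                    pd.DataFrame({"y": y}), seed=3)
    assert np.exp(res.coefficient("intercept")["mean"]) == pytest.approx(
        y.mean(), rel=0.02)


def test_spatial_effect_sums_to_zero(rng):
    g = make_grid(8, 8)
    cells = g.cell_ids
    y = rng.normal(0, 1, 64)
    df = pd.DataFrame({"y": y, "cell_id": cells})
    res = bayes.fit(bayes.ModelSpec("gaussian", "y", [],
                                    spatial_effect="icar", sampler=FAST),
                    df, grid=g, seed=4)
    gamma_mean = res.gamma_draws.mean(axis=0)
    assert abs(gamma_mean.sum()) < 1e-6 * len(cells)


def test_pc_prior_strictness_shrinks_field_scale(rng):
    g = make_grid(8, 8)
    field = gaussian_field(g, 3.0, rng)[:, 0]
    y = 0.5 * (field - field.mean()) + rng.normal(0, 0.3, 64)
    df = pd.DataFrame({"y": y, "cell_id": g.cell_ids})
    means = []
    for alpha in (0.5, 0.05, 0.005):
        spec = bayes.ModelSpec(
            "gaussian", "y", [], spatial_effect="icar",
            priors=bayes.Priors(pc_u=0.3, pc_alpha=alpha),
            sampler=bayes.SamplerConfig(chains=2, warmup=400, draws=500))
        res = bayes.fit(spec, df, grid=g, seed=5)
        sg = res.hyperparameters.set_index("parameter")
        means.append(sg.loc["sigma_gamma", "mean"])
    assert means[2] <= means[0] + 0.05
    assert means[1] <= means[0] + 0.02


def test_proportion_change_identity_and_draw_oracle(rng):
    pc = bayes.proportion_change(np.zeros(100))
    assert pc.factor == pytest.approx(1.0)
    assert pc.percent_change == pytest.approx(0.0)
    pc = bayes.proportion_change(np.full(100, np.log(1.02)))
    assert pc.percent_change == pytest.approx(2.0)
    draws = rng.normal(0.05, 0.02, 4000)
    pc = bayes.proportion_change(draws)
    assert pc.factor == pytest.approx(np.exp(draws.mean()), rel=1e-12)
    assert pc.factor_draws_mean == pytest.approx(np.exp(draws).mean(),
                                                 rel=1e-12)
    assert pc.factor_q025 == pytest.approx(
        np.quantile(np.exp(draws), 0.025), rel=1e-9)


def test_change_probability_counting_oracle(rng):
    draws = np.column_stack([
        np.abs(rng.standard_normal(500)),          # always positive
        rng.standard_normal(500),                  # symmetric about 0
        rng.normal(-0.2, 0.1, 500),                # mostly negative
    ])
    p_cell, mean_pct, se_pct = bayes.change_probability(draws)
    counting = (draws > 0).sum(axis=0) / draws.shape[0]
    np.testing.assert_allclose(p_cell, counting)
    assert p_cell[0] == 1.0
    assert p_cell[1] == pytest.approx(0.5, abs=0.1)
    assert mean_pct == pytest.approx(100 * counting.mean())


def test_r2_zero_when_fixed_effects_absent(rng):
    y = rng.normal(0, 1, 300)
    res = bayes.fit(bayes.ModelSpec("gaussian", "y", [], sampler=FAST),
                    pd.DataFrame({"y": y}), seed=6)
    r2m, _ = bayes.r2_decomposition(res)
    assert r2m == pytest.approx(0.0, abs=0.01)


def test_pure_noise_covariate_barely_moves_marginal_r2(rng):
    n = 1000
    x = rng.standard_normal(n)
    y = 0.8 * x + rng.normal(0, 1, n)
    base = bayes.fit(bayes.ModelSpec("gaussian", "y", ["x"], sampler=FAST),
                     pd.DataFrame({"y": y, "x": x}), seed=7)
    noise = rng.standard_normal(n)
    more = bayes.fit(bayes.ModelSpec("gaussian", "y", ["x", "junk"],
                                     sampler=FAST),
                     pd.DataFrame({"y": y, "x": x, "junk": noise}), seed=7)
    r2_base, _ = bayes.r2_decomposition(base)
    r2_more, _ = bayes.r2_decomposition(more)
    assert abs(r2_more - r2_base) < 0.01
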