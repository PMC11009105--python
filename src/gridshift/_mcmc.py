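"""Metropolis-within-Gibbs machinery behind :mod:`gridshift.bayes`.

Two samplers share one draw layout:

* Gaussian responses use exact block Gibbs — (beta, gamma) are drawn
  jointly from their conjugate Gaussian full conditional, the iid cell
  effect and the residual precision are conjugate too, and only the
  random-effect standard deviations need Metropolis steps (their
  penalized-complexity priors are not conjugate).
* Non-Gaussian families use adaptive random-walk Metropolis for the fixed
  effects (joint proposal, covariance adapted during warmup) and a
  chromatic update for the intrinsic-CAR field: the adjacency graph is
  greedily coloured, and all cells of one colour are updated
  simultaneously — they are conditionally independent given the rest, so
  the per-cell accept/reject vectorises.

The intrinsic CAR prior is kept proper-in-effect by re-centring the field
to sum to zero after every sweep, folding the removed mean into the
intercept (which leaves the likelihood untouched).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import expit, gammaln

# ---------------------------------------------------------------------------
# log-likelihoods (constant-in-parameter terms kept where dispersion moves)

def _loglik_rows(family, y, eta, disp):
    """Per-row log-likelihood given linear predictor eta.

    eta is capped at 60 on the log scale: far beyond any realistic linear
    predictor, so wild MH proposals score -inf-ish instead of overflowing.
    """
    eta = np.minimum(eta, 60.0)
    if family == "poisson":
        return y * eta - np.exp(eta)
    if family == "negative_binomial":
        mu = np.exp(eta)
        k = disp
        return (gammaln(y + k) - gammaln(k) - gammaln(y + 1.0)
                + k * np.log(k / (k + mu)) + y * (eta - np.log(k + mu)))
    if family == "gamma":
        mu = np.exp(eta)
        th = disp
        return (th * np.log(th) - gammaln(th) + (th - 1.0) * np.log(y)
                - th * np.log(mu) - th * y / mu)
    if family == "beta":
        mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
        a = mu * disp
        b = (1.0 - mu) * disp
        return (gammaln(disp) - gammaln(a) - gammaln(b)
                + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
    raise ValueError(f"unsupported family {family!r}")


def _log_prior_disp(disp, shape, rate):
    # Gamma(shape, rate) on the dispersion/precision parameter itself
    return (shape - 1.0) * np.log(disp) - rate * disp


def _log_prior_pc(sigma, lam):
    # PC prior: exponential(lam) density on the standard deviation
    return -lam * sigma


# ---------------------------------------------------------------------------
# graph helpers

def graph_components(W: csr_matrix) -> tuple[int, np.ndarray]:
    return connected_components(W, directed=False)


def greedy_coloring(W: csr_matrix) -> np.ndarray:
    """Greedy vertex colouring; adjacent cells never share a colour."""
    n = W.shape[0]
    indptr, indices = W.indptr, W.indices
    colors = np.full(n, -1, dtype=int)
    for v in range(n):
        used = {colors[u] for u in indices[indptr[v]:indptr[v + 1]]
                if colors[u] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[v] = c
    return colors


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar parameter.

    ``draws`` is (n_chains, n_draws); each chain is split in half.
    """
    nchain, ndraw = draws.shape
    half = ndraw // 2
    if half < 2:
        return np.nan
    sub = draws[:, : 2 * half].reshape(nchain * 2, half)
    means = sub.mean(axis=1)
    variances = sub.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / w))


# ---------------------------------------------------------------------------
# shared pieces

class _StepAdapter:
    """Robbins–Monro step-size adaptation toward a target acceptance."""

    def __init__(self, size, target, value=0.1):
        self.log_step = np.full(size, np.log(value)) if size else np.log(value)
        self.target = target
        self.count = 0

    def step(self):
        return np.exp(self.log_step)

    def update(self, accepted, warmup_active):
        if not warmup_active:
            return
        self.count += 1
        gain = 1.0 / max(10, self.count) ** 0.6 * 10.0
        self.log_step += gain * (accepted - self.target)


def _center_gamma(gamma, beta, comp_labels, n_comp, has_intercept=True):
    """Sum-to-zero per component; fold the overall shift into the intercept."""
    if n_comp == 1:
        shift = gamma.mean()
        gamma -= shift
        if has_intercept:
            beta[0] += shift
    else:
        for c in range(n_comp):
            mask = comp_labels == c
            gamma[mask] -= gamma[mask].mean()
    return gamma, beta


def _interweave_sigma_gaussian(sigma, field, resid_with_field, A, tau, lam,
                               rng, adapter, warmup_active):
    """Non-centered rescaling move for a random-effect sd (Gaussian case).

    Holding g = field/sigma fixed, propose sigma' and rescale the field;
    the iCAR/iid prior on g is scale-free, so only the likelihood, the PC
    prior and the log-scale Jacobian enter.  Interweaving this with the
    centered update breaks the mixing bottleneck between the field scale
    and the residual variance when there is one observation per cell.
    """
    prop = sigma * np.exp(adapter.step() * rng.standard_normal())
    scale = prop / sigma
    # resid_with_field = y - Xb - field[A] (- nu[A]); adding back the field
    base = resid_with_field + field[A]
    r_new = base - scale * field[A]
    d = (-0.5 * tau * (float(r_new @ r_new)
                       - float(resid_with_field @ resid_with_field))
         + _log_prior_pc(prop, lam) - _log_prior_pc(sigma, lam)
         + np.log(prop) - np.log(sigma))
    acc = 0.0
    if np.log(rng.random()) < d:
        sigma = prop
        field *= scale
        resid_with_field = r_new
        acc = 1.0
    adapter.update(acc, warmup_active)
    return sigma, field, resid_with_field


def _mh_sigma(sigma, gamma_quad, rank, lam, rng, adapter, warmup_active):
    """Log-scale random-walk MH for a random-effect sd under a PC prior.

    ``gamma_quad`` is the prior quadratic form (u'Qu or sum of squares);
    ``rank`` the prior's rank.
    """
    def logpost(s):
        return (-rank * np.log(s) - gamma_quad / (2.0 * s * s)
                + _log_prior_pc(s, lam) + np.log(s))  # + Jacobian

    prop = sigma * np.exp(adapter.step() * rng.standard_normal())
    acc = 0.0
    if np.log(rng.random()) < logpost(prop) - logpost(sigma):
        sigma = prop
        acc = 1.0
    adapter.update(acc, warmup_active)
    return sigma


# ---------------------------------------------------------------------------
# Gaussian block-Gibbs sampler

def _slice_1d(x0, logf, rng, w=1.0, max_steps=50):
    """Univariate slice sampling with stepping-out and shrinkage."""
    f0 = logf(x0)
    level = f0 - rng.exponential()
    left = x0 - w * rng.random()
    right = left + w
    j = max_steps
    while j > 0 and logf(left) > level:
        left -= w
        j -= 1
    j = max_steps
    while j > 0 and logf(right) > level:
        right += w
        j -= 1
    while True:
        x1 = left + rng.random() * (right - left)
        if logf(x1) > level:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _run_gaussian_collapsed(y, X, A, Q, comp_labels, n_comp, priors,
                            n_warmup, n_draws, rng):
    """Collapsed chain for the Gaussian + iCAR model, one row per cell.

    With a single observation per cell the residual sd and the field sd
    trade off along a long, nearly flat posterior ridge, which defeats
    centered Gibbs updates.  Here the model is rotated into the
    eigenbasis of Q, where the marginal posterior of (log tau,
    log sigma_gamma) — with beta and gamma integrated out exactly — costs
    O(n p) per evaluation.  Slice sampling then traverses the ridge
    freely, and (beta, gamma) are redrawn exactly from their Gaussian
    conditionals.  The sum-to-zero constraint is exact: the null
    eigenvectors of Q (per-component constants) carry no field component.
    """
    n, p = X.shape
    nc = Q.shape[0]
    lam = priors.pc_lambda()
    prior_prec = np.full(p, 1.0 / priors.beta_var)
    prior_prec[0] = 1.0 / priors.intercept_var

    # reorder rows into cell order (A is a bijection here)
    order = np.argsort(A)
    yc = y[order]
    Xc = X[order]
    evals, V = np.linalg.eigh(Q.toarray())
    evals = np.clip(evals, 0.0, None)
    pos = evals > 1e-9 * max(evals.max(), 1.0)
    y_t = V.T @ yc
    X_t = V.T @ Xc

    def logpost(lt, ls):
        tau = np.exp(lt)
        sg2 = np.exp(2.0 * ls)
        d = np.full(nc, 1.0 / tau)
        d[pos] += sg2 / evals[pos]
        dinv = 1.0 / d
        Pb = (X_t.T * dinv) @ X_t + np.diag(prior_prec)
        bb = X_t.T @ (dinv * y_t)
        cfb = cho_factor(Pb, lower=True, check_finite=False)
        quad_b = float(bb @ cho_solve(cfb, bb, check_finite=False))
        logdet_pb = 2.0 * np.log(np.diag(cfb[0])).sum()
        ll = (-0.5 * np.log(d).sum() - 0.5 * float(y_t @ (dinv * y_t))
              - 0.5 * logdet_pb + 0.5 * quad_b)
        lp = (priors.gauss_prec_shape * lt - priors.gauss_prec_rate * tau
              + _log_prior_pc(np.exp(ls), lam) + ls)
        return ll + lp

    lt = np.log(1.0 / max(np.var(yc) * 0.5, 1e-6))
    ls = np.log(0.5)
    out = {k: [] for k in ("beta", "gamma", "nu", "sigma", "sigma_gamma",
                           "sigma_nu")}
    for it in range(n_warmup + n_draws):
        lt = _slice_1d(lt, lambda v: logpost(v, ls), rng, w=1.5)
        ls = _slice_1d(ls, lambda v: logpost(lt, v), rng, w=0.75)
        tau = np.exp(lt)
        sg2 = np.exp(2.0 * ls)
        d = np.full(nc, 1.0 / tau)
        d[pos] += sg2 / evals[pos]
        dinv = 1.0 / d
        Pb = (X_t.T * dinv) @ X_t + np.diag(prior_prec)
        bb = X_t.T @ (dinv * y_t)
        cfb = cho_factor(Pb, lower=True, check_finite=False)
        mean_b = cho_solve(cfb, bb, check_finite=False)
        beta = mean_b + solve_triangular(cfb[0], rng.standard_normal(p),
                                         lower=True, trans="T",
                                         check_finite=False)
        r_t = y_t - X_t @ beta
        gamma_t = np.zeros(nc)
        prec_g = tau + evals[pos] / sg2
        mean_g = tau * r_t[pos] / prec_g
        gamma_t[pos] = (mean_g + rng.standard_normal(pos.sum())
                        / np.sqrt(prec_g))
        gamma = V @ gamma_t
        if it >= n_warmup:
            out["beta"].append(beta)
            out["gamma"].append(gamma)
            out["nu"].append(np.zeros(0))
            out["sigma"].append(float(np.exp(-lt / 2.0)))
            out["sigma_gamma"].append(float(np.exp(ls)))
            out["sigma_nu"].append(0.0)
    return {k: np.asarray(v) for k, v in out.items()}


def _run_gaussian_collapsed_dense(y, X, A, Q, comp_labels, n_comp, priors,
                                  n_warmup, n_draws, rng):
    """Dense collapsed chain (rows not one-per-cell): adaptive MH on the
    joint marginal of (log tau, log sigma_gamma) with (beta, gamma)
    integrated out via the full (p + nc) precision matrix."""
    n, p = X.shape
    nc = Q.shape[0]
    dim = p + nc
    lam = priors.pc_lambda()
    prior_prec = np.full(p, 1.0 / priors.beta_var)
    prior_prec[0] = 1.0 / priors.intercept_var
    m_c = np.bincount(A, minlength=nc).astype(float)
    XtA = np.zeros((p, nc))
    np.add.at(XtA.T, A, X)
    Qd = Q.toarray()
    rank = nc - n_comp

    M1 = np.zeros((dim, dim))
    M1[:p, :p] = X.T @ X
    M1[:p, p:] = XtA
    M1[p:, :p] = XtA.T
    M1[p:, p:] = np.diag(m_c)
    M2 = np.zeros((dim, dim))
    M2[p:, p:] = Qd
    M3 = np.diag(np.concatenate([prior_prec, np.zeros(nc)]))
    bvec = np.concatenate([X.T @ y, np.bincount(A, weights=y,
                                                minlength=nc)])
    yy = float(y @ y)

    def logpost(lt, ls):
        tau = np.exp(lt)
        sg = np.exp(ls)
        P = tau * M1 + M2 / (sg * sg) + M3
        cf = cho_factor(P, lower=True, check_finite=False)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        b = tau * bvec
        mean = cho_solve(cf, b, check_finite=False)
        quad = float(b @ mean)
        ll = (0.5 * n * lt - 0.5 * tau * yy - rank * ls
              - 0.5 * logdet + 0.5 * quad)
        lp = (priors.gauss_prec_shape * lt - priors.gauss_prec_rate * tau
              + _log_prior_pc(sg, lam) + ls)  # incl. Jacobians
        return ll + lp, cf, mean

    lt = np.log(1.0 / max(np.var(y) * 0.5, 1e-6))
    ls = np.log(0.5)
    cur, cf, mean = logpost(lt, ls)
    adapter = _StepAdapter(None, 0.35, 0.4)
    Lh = np.eye(2)  # proposal shape, adapted to the (lt, ls) ridge
    hist = []
    out = {k: [] for k in ("beta", "gamma", "nu", "sigma", "sigma_gamma",
                           "sigma_nu")}
    for it in range(n_warmup + n_draws):
        warm = it < n_warmup
        if warm:
            hist.append((lt, ls))
            if it >= 150 and it % 50 == 0:
                emp = np.cov(np.asarray(hist[-300:]).T) + 1e-6 * np.eye(2)
                Lh = np.linalg.cholesky(emp)
                adapter.log_step = np.log(1.7)  # ~2.38/sqrt(2) on shape
        step = adapter.step()
        dlt, dls = step * (Lh @ rng.standard_normal(2))
        lt_p = lt + dlt
        ls_p = ls + dls
        try:
            prop, cf_p, mean_p = logpost(lt_p, ls_p)
            ok = np.isfinite(prop)
        except np.linalg.LinAlgError:
            ok = False
        if ok and np.log(rng.random()) < prop - cur:
            lt, ls, cur, cf, mean = lt_p, ls_p, prop, cf_p, mean_p
            adapter.update(1.0, warm)
        else:
            adapter.update(0.0, warm)
        z = rng.standard_normal(dim)
        draw = mean + solve_triangular(cf[0], z, lower=True, trans="T",
                                       check_finite=False)
        beta, gamma = draw[:p].copy(), draw[p:].copy()
        gamma, beta = _center_gamma(gamma, beta, comp_labels, n_comp)
        if not warm:
            out["beta"].append(beta)
            out["gamma"].append(gamma)
            out["nu"].append(np.zeros(0))
            out["sigma"].append(float(np.exp(-lt / 2.0)))
            out["sigma_gamma"].append(float(np.exp(ls)))
            out["sigma_nu"].append(0.0)
    return {k: np.asarray(v) for k, v in out.items()}


def run_gaussian_chain(y, X, A, Q, W, comp_labels, n_comp, mode, priors,
                       n_warmup, n_draws, rng, init_beta=None):
    """One chain for the identity-link Gaussian model.

    mode in {"none", "icar", "icar_plus_iid"}.  Returns a dict of draws.
    The pure-iCAR case uses the collapsed sampler above.
    """
    if mode == "icar":
        nc = Q.shape[0]
        if len(y) == nc and np.array_equal(np.sort(A), np.arange(nc)):
            return _run_gaussian_collapsed(y, X, A, Q, comp_labels, n_comp,
                                           priors, n_warmup, n_draws, rng)
        return _run_gaussian_collapsed_dense(y, X, A, Q, comp_labels,
                                             n_comp, priors, n_warmup,
                                             n_draws, rng)
    n, p = X.shape
    spatial = mode != "none"
    nc = Q.shape[0] if spatial else 0
    iid = mode == "icar_plus_iid"
    lam = priors.pc_lambda()

    prior_prec = np.full(p, 1.0 / priors.beta_var)
    prior_prec[0] = 1.0 / priors.intercept_var

    XtX = X.T @ X
    Xty = X.T @ y
    if spatial:
        m_c = np.bincount(A, minlength=nc).astype(float)
        XtA = np.zeros((p, nc))
        np.add.at(XtA.T, A, X)          # sum of X rows per cell
        Qd = Q.toarray() if hasattr(Q, "toarray") else np.asarray(Q)
        rank = nc - n_comp

    beta = np.zeros(p) if init_beta is None else init_beta.copy()
    gamma = np.zeros(nc)
    nu = np.zeros(nc)
    tau = 1.0 / max(np.var(y), 1e-6)
    sigma_g = 0.5
    sigma_nu = 0.5
    ad_g = _StepAdapter(None, 0.44, 0.3)
    ad_nu = _StepAdapter(None, 0.44, 0.3)
    ad_gi = _StepAdapter(None, 0.44, 0.3)
    ad_nui = _StepAdapter(None, 0.44, 0.3)

    total = n_warmup + n_draws
    out = {k: [] for k in ("beta", "gamma", "nu", "sigma", "sigma_gamma",
                           "sigma_nu")}
    for it in range(total):
        warm = it < n_warmup
        r = y - (nu[A] if iid else 0.0)
        if spatial:
            dim = p + nc
            P = np.zeros((dim, dim))
            P[:p, :p] = tau * XtX + np.diag(prior_prec)
            P[:p, p:] = tau * XtA
            P[p:, :p] = P[:p, p:].T
            P[p:, p:] = Qd / (sigma_g * sigma_g)
            P[p:, p:][np.diag_indices(nc)] += tau * m_c
            b = np.concatenate([tau * (X.T @ r),
                                tau * np.bincount(A, weights=r,
                                                  minlength=nc)])
            cf = cho_factor(P, lower=True)
            mean = cho_solve(cf, b)
            z = rng.standard_normal(dim)
            draw = mean + solve_triangular(cf[0], z, lower=True, trans="T")
            beta, gamma = draw[:p], draw[p:]
            gamma, beta = _center_gamma(gamma, beta, comp_labels, n_comp)
        else:
            P = tau * XtX + np.diag(prior_prec)
            b = tau * (X.T @ r)
            cf = cho_factor(P, lower=True)
            mean = cho_solve(cf, b)
            beta = mean + solve_triangular(cf[0], rng.standard_normal(p),
                                           lower=True, trans="T")

        eta_fixed = X @ beta + (gamma[A] if spatial else 0.0)
        if iid:
            e = y - eta_fixed
            prec = m_c * tau + 1.0 / (sigma_nu * sigma_nu)
            mean_nu = tau * np.bincount(A, weights=e, minlength=nc) / prec
            nu = mean_nu + rng.standard_normal(nc) / np.sqrt(prec)
            nu -= nu.mean()

        resid = y - eta_fixed - (nu[A] if iid else 0.0)
        tau = rng.gamma(priors.gauss_prec_shape + 0.5 * n,
                        1.0 / (priors.gauss_prec_rate
                               + 0.5 * float(resid @ resid)))

        if spatial:
            quad = float(gamma @ (Qd @ gamma))
            sigma_g = _mh_sigma(sigma_g, quad, rank, lam, rng, ad_g, warm)
            sigma_g, gamma, resid = _interweave_sigma_gaussian(
                sigma_g, gamma, resid, A, tau, lam, rng, ad_gi, warm)
        if iid:
            sigma_nu = _mh_sigma(sigma_nu, float(nu @ nu), nc, lam, rng,
                                 ad_nu, warm)
            sigma_nu, nu, resid = _interweave_sigma_gaussian(
                sigma_nu, nu, resid, A, tau, lam, rng, ad_nui, warm)

        if not warm:
            out["beta"].append(beta.copy())
            out["gamma"].append(gamma.copy())
            out["nu"].append(nu.copy())
            out["sigma"].append(1.0 / np.sqrt(tau))
            out["sigma_gamma"].append(sigma_g)
            out["sigma_nu"].append(sigma_nu)
    return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# non-Gaussian Metropolis-within-Gibbs

def run_glmm_chain(family, y, X, A, W, comp_labels, n_comp, mode, priors,
                   n_warmup, n_draws, rng, init_beta, init_disp,
                   prop_cov=None):
    """One chain for Poisson / negative-binomial / Gamma / Beta models."""
    n, p = X.shape
    spatial = mode != "none"
    iid = mode == "icar_plus_iid"
    nc = W.shape[0] if spatial else 0
    lam = priors.pc_lambda()
    has_disp = family != "poisson"

    prior_prec = np.full(p, 1.0 / priors.beta_var)
    prior_prec[0] = 1.0 / priors.intercept_var

    beta = init_beta.copy()
    gamma = np.zeros(nc)
    nu = np.zeros(nc)
    disp = float(init_disp)
    sigma_g = 0.5
    sigma_nu = 0.5

    if spatial:
        colors = greedy_coloring(W)
        color_sets = [np.flatnonzero(colors == c)
                      for c in range(colors.max() + 1)]
        neigh_counts = np.asarray(W.sum(axis=1)).ravel()
        rank = nc - n_comp
        rows_of_cell = A  # row -> cell index
        rows_by_color = [np.flatnonzero(np.isin(A, cells))
                         for cells in color_sets]
        # position of each row's cell within its colour set
        cell_pos = np.empty(nc, dtype=int)
        for cells in color_sets:
            cell_pos[cells] = np.arange(cells.size)

    if prop_cov is None:
        prop_cov = np.eye(p) * 0.01
    Lprop = np.linalg.cholesky(prop_cov + 1e-10 * np.eye(p))
    ad_beta = _StepAdapter(None, 0.234, 2.38 / np.sqrt(p))
    ad_coord = _StepAdapter(p, 0.44, 0.1)
    ad_gcell = _StepAdapter(nc if spatial else 0, 0.44, 0.3)
    ad_nucell = _StepAdapter(nc if iid else 0, 0.44, 0.3)
    ad_disp = _StepAdapter(None, 0.44, 0.3)
    ad_sg = _StepAdapter(None, 0.44, 0.3)
    ad_snu = _StepAdapter(None, 0.44, 0.3)
    ad_sgi = _StepAdapter(None, 0.44, 0.3)
    ad_snui = _StepAdapter(None, 0.44, 0.3)

    eta = X @ beta
    if spatial:
        eta = eta + gamma[A]
    ll_rows = _loglik_rows(family, y, eta, disp)

    beta_hist = []
    total = n_warmup + n_draws
    out = {k: [] for k in ("beta", "gamma", "nu", "disp", "sigma_gamma",
                           "sigma_nu")}
    for it in range(total):
        warm = it < n_warmup

        # ---- fixed effects: joint adaptive RW
        step = ad_beta.step()
        prop = beta + step * (Lprop @ rng.standard_normal(p))
        eta_prop = eta + X @ (prop - beta)
        ll_prop = _loglik_rows(family, y, eta_prop, disp)
        dlp = (ll_prop.sum() - ll_rows.sum()
               - 0.5 * float(prop @ (prior_prec * prop))
               + 0.5 * float(beta @ (prior_prec * beta)))
        if np.log(rng.random()) < dlp:
            beta, eta, ll_rows = prop, eta_prop, ll_prop
            ad_beta.update(1.0, warm)
        else:
            ad_beta.update(0.0, warm)
        if warm:
            beta_hist.append(beta.copy())
            if it >= 200 and it % 100 == 0 and len(beta_hist) > 50:
                emp = np.cov(np.asarray(beta_hist[-400:]).T)
                emp = np.atleast_2d(emp) + 1e-8 * np.eye(p)
                Lprop = np.linalg.cholesky(emp)
                ad_beta.log_step = np.log(2.38 / np.sqrt(p))

        # ---- per-coordinate refresh sweep (cheap, improves tail mixing)
        steps_c = ad_coord.step()
        for j in range(p):
            dz = steps_c[j] * rng.standard_normal()
            bj_new = beta[j] + dz
            eta_new = eta + X[:, j] * dz
            ll_new = _loglik_rows(family, y, eta_new, disp)
            dlp = (ll_new.sum() - ll_rows.sum()
                   - 0.5 * prior_prec[j] * (bj_new ** 2 - beta[j] ** 2))
            acc = 0.0
            if np.log(rng.random()) < dlp:
                beta[j] = bj_new
                eta, ll_rows = eta_new, ll_new
                acc = 1.0
            if warm:
                ad_coord.log_step[j] += (10.0 / max(10, it + 1) ** 0.6
                                         * (acc - ad_coord.target))

        # ---- spatial field: chromatic single-site MH
        if spatial:
            inv_sg2 = 1.0 / (sigma_g * sigma_g)
            for ci, cells in enumerate(color_sets):
                idx = rows_by_color[ci]
                steps = ad_gcell.step()[cells]
                dg = steps * rng.standard_normal(cells.size)
                eta_new = eta[idx] + dg[cell_pos[rows_of_cell[idx]]]
                ll_new = _loglik_rows(family, y[idx], eta_new, disp)
                dll_cell = np.bincount(rows_of_cell[idx],
                                       weights=ll_new - ll_rows[idx],
                                       minlength=nc)[cells]
                s_nb = W[cells].dot(gamma)  # no same-colour neighbours
                g_old = gamma[cells]
                g_new = g_old + dg
                dprior = -0.5 * inv_sg2 * (
                    neigh_counts[cells] * (g_new ** 2 - g_old ** 2)
                    - 2.0 * s_nb * (g_new - g_old))
                accept = np.log(rng.random(cells.size)) < dll_cell + dprior
                if accept.any():
                    gamma[cells[accept]] = g_new[accept]
                    row_acc = accept[cell_pos[rows_of_cell[idx]]]
                    eta[idx[row_acc]] = eta_new[row_acc]
                    ll_rows[idx[row_acc]] = ll_new[row_acc]
                if warm:
                    mask = np.zeros(nc, bool)
                    mask[cells] = True
                    full_acc = np.zeros(cells.size)
                    full_acc[accept] = 1.0
                    ad_gcell.log_step[mask] += (
                        10.0 / max(10, it + 1) ** 0.6
                        * (full_acc - ad_gcell.target))
            gamma, beta = _center_gamma(gamma, beta, comp_labels, n_comp)
            eta = X @ beta + gamma[rows_of_cell] + (nu[rows_of_cell]
                                                    if iid else 0.0)
            ll_rows = _loglik_rows(family, y, eta, disp)

        # ---- iid cell effects: simultaneous independent MH
        if iid:
            steps = ad_nucell.step()
            dn = steps * rng.standard_normal(nc)
            eta_new = eta + dn[rows_of_cell]
            ll_new = _loglik_rows(family, y, eta_new, disp)
            dll_cell = np.bincount(rows_of_cell, weights=ll_new - ll_rows,
                                   minlength=nc)
            nu_new = nu + dn
            dprior = (-(nu_new ** 2) + nu ** 2) / (2.0 * sigma_nu ** 2)
            accept = np.log(rng.random(nc)) < dll_cell + dprior
            if accept.any():
                nu = np.where(accept, nu_new, nu)
                eta = X @ beta + gamma[rows_of_cell] + nu[rows_of_cell]
                ll_rows = _loglik_rows(family, y, eta, disp)
            if warm:
                ad_nucell.log_step += (10.0 / max(10, it + 1) ** 0.6
                                       * (accept.astype(float)
                                          - ad_nucell.target))

        # ---- dispersion
        if has_disp:
            prop_d = disp * np.exp(ad_disp.step() * rng.standard_normal())
            ll_prop = _loglik_rows(family, y, eta, prop_d)
            dlp = (ll_prop.sum() - ll_rows.sum()
                   + _log_prior_disp(prop_d, priors.disp_shape,
                                     priors.disp_rate)
                   - _log_prior_disp(disp, priors.disp_shape,
                                     priors.disp_rate)
                   + np.log(prop_d) - np.log(disp))
            if np.log(rng.random()) < dlp:
                disp = prop_d
                ll_rows = ll_prop
                ad_disp.update(1.0, warm)
            else:
                ad_disp.update(0.0, warm)

        # ---- random-effect scales (centered MH + non-centered interweave)
        if spatial:
            quad = float((neigh_counts * gamma * gamma).sum()
                         - gamma @ (W @ gamma))
            sigma_g = _mh_sigma(sigma_g, quad, rank, lam, rng, ad_sg, warm)
            prop_s = sigma_g * np.exp(ad_sgi.step() * rng.standard_normal())
            scale = prop_s / sigma_g
            eta_new = eta + (scale - 1.0) * gamma[rows_of_cell]
            ll_new = _loglik_rows(family, y, eta_new, disp)
            d = (ll_new.sum() - ll_rows.sum()
                 + _log_prior_pc(prop_s, lam) - _log_prior_pc(sigma_g, lam)
                 + np.log(prop_s) - np.log(sigma_g))
            if np.log(rng.random()) < d:
                sigma_g = prop_s
                gamma = gamma * scale
                eta, ll_rows = eta_new, ll_new
                ad_sgi.update(1.0, warm)
            else:
                ad_sgi.update(0.0, warm)
        if iid:
            sigma_nu = _mh_sigma(sigma_nu, float(nu @ nu), nc, lam, rng,
                                 ad_snu, warm)
            prop_s = sigma_nu * np.exp(ad_snui.step()
                                       * rng.standard_normal())
            scale = prop_s / sigma_nu
            eta_new = eta + (scale - 1.0) * nu[rows_of_cell]
            ll_new = _loglik_rows(family, y, eta_new, disp)
            d = (ll_new.sum() - ll_rows.sum()
                 + _log_prior_pc(prop_s, lam) - _log_prior_pc(sigma_nu, lam)
                 + np.log(prop_s) - np.log(sigma_nu))
            if np.log(rng.random()) < d:
                sigma_nu = prop_s
                nu = nu * scale
                eta, ll_rows = eta_new, ll_new
                ad_snui.update(1.0, warm)
            else:
                ad_snui.update(0.0, warm)

        if not warm:
            out["beta"].append(beta.copy())
            out["gamma"].append(gamma.copy())
            out["nu"].append(nu.copy())
            out["disp"].append(disp)
            out["sigma_gamma"].append(sigma_g)
            out["sigma_nu"].append(sigma_nu)
    return {k: np.asarray(v) for k, v in out.items()}
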