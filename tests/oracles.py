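"""Independent oracles used by the tests.

Each function computes an expected value by a route that shares no code with
the implementation under test: iterative grid search for logistic ML, dense
numerical integration for posterior means, and exhaustive rank enumeration for
the Mann-Whitney null distribution.
"""

import itertools

import numpy as np
from scipy import stats


def loglik_logistic(coef, X, y):
    eta = X @ coef
    return float(np.sum(y * (-np.logaddexp(0, -eta)) + (1 - y) * (-np.logaddexp(0, eta))))


def grid_logistic(X, y, half_width=4.0, n_grid=11, n_zoom=16, shrink=0.4):
    """Maximize the logistic likelihood by iterative grid refinement.

    Each zoom recenters on the best grid point and multiplies the box
    half-width by ``shrink``; with shrink > 2/(n_grid-1) the maximizer always
    stays inside the next box, so the final resolution is about
    half_width * shrink**n_zoom (~1e-5 for the defaults).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    d = X.shape[1]
    center = np.zeros(d)
    hw = half_width
    best_ll = -np.inf
    for _ in range(n_zoom):
        axes = [np.linspace(c - hw, c + hw, n_grid) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        coefs = np.stack([m.ravel() for m in mesh], axis=1)
        eta = X @ coefs.T
        ll = (
            y[:, None] * (-np.logaddexp(0, -eta))
            + (1 - y)[:, None] * (-np.logaddexp(0, eta))
        ).sum(axis=0)
        i = int(np.argmax(ll))
        center = coefs[i]
        best_ll = float(ll[i])
        hw *= shrink
    return center, best_ll


def fine_grid_eap(pattern, a, b, n_nodes=481, lo=-6.0, hi=6.0, mean=0.0, sd=1.0):
    """Posterior mean of the trait by dense fixed-grid integration."""
    grid = np.linspace(lo, hi, n_nodes)
    w = stats.norm.pdf(grid, mean, sd)
    w = w / w.sum()
    P = 1.0 / (1.0 + np.exp(-np.outer(a, grid) + (a * b)[:, None]))
    pattern = np.asarray(pattern, float)
    obs = ~np.isnan(pattern)
    lik = np.ones_like(grid)
    for j in np.flatnonzero(obs):
        lik = lik * (P[j] if pattern[j] == 1 else 1 - P[j])
    post = w * lik
    post = post / post.sum()
    return float(post @ grid)


def mannwhitney_exact_enumeration(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            for comb in itertools.combinations(range(n1 + n2), n1)
        ]
    )
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return float(min(1.0, p)), float(u_obs)


def grid_marginal_2pl(Y, a_grid, b_grid, n_nodes=61, lo=-5.0, hi=5.0):
    """Marginal log-likelihood surface for a 2PL with all items sharing (a, b).

    Brute-force oracle for calibration sanity checks on tiny same-parameter
    scales: returns the (a, b) pair on the grid with maximal marginal
    likelihood under a standard-normal trait.
    """
    Y = np.asarray(Y, float)
    grid = np.linspace(lo, hi, n_nodes)
    w = stats.norm.pdf(grid)
    w = w / w.sum()
    best = (-np.inf, None, None)
    for a in a_grid:
        for b in b_grid:
            p = 1.0 / (1.0 + np.exp(-a * (grid - b)))
            logp, logq = np.log(p), np.log(1 - p)
            ll_pn = Y[:, :, None] * logp[None, None, :] + (1 - Y)[:, :, None] * logq[None, None, :]
            ll_pq = ll_pn.sum(axis=1)  # (n, nodes)
            mx = ll_pq.max(axis=1, keepdims=True)
            marg = float(np.sum(mx.ravel() + np.log(np.exp(ll_pq - mx) @ w)))
            if marg > best[0]:
                best = (marg, a, b)
    return best
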