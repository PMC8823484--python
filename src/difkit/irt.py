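"""Two-parameter logistic (2PL) IRT calibration and EAP ability scoring.

The measurement model for dichotomous item ``i`` is

    P(Y_i = 1 | theta) = 1 / (1 + exp(-a_i (theta - b_i)))

with discrimination ``a_i`` and difficulty ``b_i``.  Items are calibrated by
marginal maximum likelihood via the Bock-Aitkin EM algorithm: the latent trait
is integrated over a fixed grid of equally spaced quadrature nodes carrying
normal prior weights, and each M-step is a weighted logistic regression of the
expected correct counts on the node locations.

Two fits are provided: a single-group calibration, and a multi-group
calibration in which a designated set of DIF items receives one parameter pair
per group level while the remaining anchor items are constrained equal across
groups.  The trait metric is identified by fixing the reference group's prior
to N(0, 1); focal-group prior means and SDs are estimated freely through the
anchors.  EAP (expected a posteriori) scores are posterior means over the same
grid, using each person's group-specific parameters and prior when available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

from ._optim import newton_logistic
from .exceptions import (
    ConvergenceWarning,
    DegenerateItemError,
    InsufficientDataError,
    NoAnchorError,
    StateError,
)
from .scale import ResponseMatrix

__all__ = [
    "QuadratureGrid",
    "ItemParameters",
    "AbilityEstimates",
    "TwoParameterLogistic",
    "fit_2pl",
    "fit_2pl_multigroup",
    "eap_scores",
    "item_curve",
    "tcc",
]

_SINGLE = "__all__"  # prior key for single-group fits


def _sigmoid(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed-node quadrature over the latent trait.

    Equally spaced nodes on ``[lo, hi]`` with weights proportional to the
    normal density; 49 nodes on [-6, 6] by default.
    """

    n_nodes: int = 49
    lo: float = -6.0
    hi: float = 6.0

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_nodes)

    def weights(self, mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
        z = (self.nodes - mean) / sd
        w = np.exp(-0.5 * z * z)
        return w / w.sum()


@dataclass
class ItemParameters:
    """Fitted 2PL parameters, possibly group-specific for DIF items.

    Anchor (non-DIF) items have a single shared ``(a, b)`` pair stored in
    ``a``/``b``; items listed in ``dif_items`` (1-based indices) additionally
    carry one pair per group level in ``group_a``/``group_b`` (full-length
    arrays equal to the shared values on anchors).
    """

    item_ids: np.ndarray
    a: np.ndarray
    b: np.ndarray
    grid: QuadratureGrid
    dif_items: frozenset = field(default_factory=frozenset)
    group_levels: tuple | None = None
    group_a: dict | None = None
    group_b: dict | None = None
    prior_mean: dict = field(default_factory=lambda: {_SINGLE: 0.0})
    prior_sd: dict = field(default_factory=lambda: {_SINGLE: 1.0})
    log_likelihood: float = np.nan
    n_cycles: int = 0
    converged: bool = True
    low_discrimination_items: tuple = ()

    @property
    def n_items(self) -> int:
        return len(self.a)

    @property
    def multigroup(self) -> bool:
        return self.group_levels is not None

    def params_for(self, level=None):
        """(a, b) arrays for one group level (or the shared pair)."""
        if level is None or not self.multigroup:
            return self.a, self.b
        if level not in self.group_a:
            raise KeyError(f"unknown group level {level!r}")
        return self.group_a[level], self.group_b[level]

    def prior_for(self, level=None):
        key = _SINGLE if (level is None or not self.multigroup) else level
        return self.prior_mean[key], self.prior_sd[key]

    # -- serialization ------------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        rows = []
        levels = self.group_levels if self.multigroup else [None]
        for level in levels:
            a, b = self.params_for(level)
            for j in range(self.n_items):
                rows.append(
                    {
                        "item_id": str(self.item_ids[j]),
                        "group": "" if level is None else str(level),
                        "a": a[j],
                        "b": b[j],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_json(self) -> dict:
        return {
            "item_ids": [str(i) for i in self.item_ids],
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "grid": {"n_nodes": self.grid.n_nodes, "lo": self.grid.lo, "hi": self.grid.hi},
            "dif_items": sorted(self.dif_items),
            "group_levels": list(self.group_levels) if self.multigroup else None,
            "group_a": {str(g): v.tolist() for g, v in (self.group_a or {}).items()},
            "group_b": {str(g): v.tolist() for g, v in (self.group_b or {}).items()},
            "prior_mean": {str(k): v for k, v in self.prior_mean.items()},
            "prior_sd": {str(k): v for k, v in self.prior_sd.items()},
            "log_likelihood": self.log_likelihood,
            "n_cycles": self.n_cycles,
            "converged": self.converged,
            "low_discrimination_items": list(self.low_discrimination_items),
        }

    @classmethod
    def from_json(cls, d: dict) -> "ItemParameters":
        levels = d.get("group_levels")
        return cls(
            item_ids=np.array(d["item_ids"], dtype=object),
            a=np.array(d["a"], dtype=float),
            b=np.array(d["b"], dtype=float),
            grid=QuadratureGrid(**d["grid"]),
            dif_items=frozenset(d.get("dif_items", ())),
            group_levels=tuple(levels) if levels is not None else None,
            group_a={g: np.array(v) for g, v in d.get("group_a", {}).items()} or None,
            group_b={g: np.array(v) for g, v in d.get("group_b", {}).items()} or None,
            prior_mean=dict(d["prior_mean"]),
            prior_sd=dict(d["prior_sd"]),
            log_likelihood=d.get("log_likelihood", np.nan),
            n_cycles=d.get("n_cycles", 0),
            converged=d.get("converged", True),
            low_discrimination_items=tuple(d.get("low_discrimination_items", ())),
        )


@dataclass
class AbilityEstimates:
    """EAP trait estimates with posterior SDs; all-missing persons get NaN."""

    theta: np.ndarray
    posterior_sd: np.ndarray
    excluded: tuple = ()


# ---------------------------------------------------------------------------
# internal EM machinery
# ---------------------------------------------------------------------------


def _as_matrix(rm) -> np.ndarray:
    if isinstance(rm, ResponseMatrix):
        if not rm.scored:
            raise StateError("2PL calibration requires a scored matrix")
        return rm.values
    return np.asarray(rm, dtype=float)


def _item_ids(rm, k) -> np.ndarray:
    if isinstance(rm, ResponseMatrix):
        return rm.item_ids
    return np.array([f"item_{j}" for j in range(1, k + 1)], dtype=object)


def _check_degenerate(Y: np.ndarray, item_ids) -> None:
    bad = []
    for j in range(Y.shape[1]):
        col = Y[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0 or obs.min() == obs.max():
            bad.append(str(item_ids[j]))
    if bad:
        raise DegenerateItemError(bad)


def _log_pq(a, c, nodes):
    """log P and log(1-P) as (k, Q) arrays for slope/intercept parameters."""
    eta = np.outer(a, nodes) + c[:, None]
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    return log_p, log_q


def _posterior(Y0, M, a, c, nodes, log_w):
    """Posterior over nodes for each person plus the marginal log-likelihood."""
    log_p, log_q = _log_pq(a, c, nodes)
    joint = (Y0 * M) @ log_p + ((1.0 - Y0) * M) @ log_q + log_w[None, :]
    mx = joint.max(axis=1, keepdims=True)
    ex = np.exp(joint - mx)
    denom = ex.sum(axis=1, keepdims=True)
    post = ex / denom
    marginal = float(np.sum(mx.ravel() + np.log(denom.ravel())))
    return post, marginal


def _mstep_item(nodes, r, n, a0, c0):
    X = np.column_stack([nodes, np.ones_like(nodes)])
    res = newton_logistic(X, r, n, coef0=np.array([a0, c0]), tol=1e-9, max_iter=60)
    return float(res.coef[0]), float(res.coef[1])


def _start_values(Y: np.ndarray):
    pbar = np.nanmean(Y, axis=0)
    pbar = np.clip(pbar, 0.02, 0.98)
    c = np.log(pbar / (1.0 - pbar))
    return np.ones_like(c), c


def fit_2pl(
    rm,
    grid: QuadratureGrid = QuadratureGrid(),
    tol: float = 1e-4,
    max_iter: int = 500,
    low_discrimination_floor: float = 0.2,
) -> ItemParameters:
    """Single-group 2PL calibration by marginal maximum likelihood EM.

    Raises :class:`DegenerateItemError` when an item shows only one response
    category; emits :class:`ConvergenceWarning` (never silent success) when the
    parameter changes have not fallen below ``tol`` within ``max_iter`` cycles.
    """
    Y = _as_matrix(rm)
    ids = _item_ids(rm, Y.shape[1])
    _check_degenerate(Y, ids)
    M = (~np.isnan(Y)).astype(float)
    Y0 = np.nan_to_num(Y)
    nodes = grid.nodes
    log_w = np.log(grid.weights())

    a, c = _start_values(Y)
    prev_ll = -np.inf
    converged = False
    cycles = 0
    for cycles in range(1, max_iter + 1):
        post, ll = _posterior(Y0, M, a, c, nodes, log_w)
        if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased ({prev_ll} -> {ll}); optimizer failure"
            )
        prev_ll = ll
        R = (Y0 * M).T @ post
        N = M.T @ post
        new_a = a.copy()
        new_c = c.copy()
        for j in range(len(a)):
            new_a[j], new_c[j] = _mstep_item(nodes, R[j], N[j], a[j], c[j])
        delta = max(np.max(np.abs(new_a - a)), np.max(np.abs(new_c - c)))
        a, c = new_a, new_c
        if delta < tol:
            converged = True
            break
    _, ll = _posterior(Y0, M, a, c, nodes, log_w)
    if not converged:
        warnings.warn(
            f"2PL EM stopped after {cycles} cycles without reaching tol={tol}",
            ConvergenceWarning,
        )
    low = tuple(
        str(ids[j]) for j in range(len(a)) if abs(a[j]) < low_discrimination_floor
    )
    if low:
        warnings.warn(f"low-discrimination items (|a| < {low_discrimination_floor}): {low}")
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(a != 0, -c / a, np.nan)
    return ItemParameters(
        item_ids=ids,
        a=a,
        b=b,
        grid=grid,
        log_likelihood=ll,
        n_cycles=cycles,
        converged=converged,
        low_discrimination_items=low,
    )


def _group_codes(group, levels=None):
    """Map a label vector to (codes, levels); reference level first."""
    g = np.asarray(group)
    if levels is None:
        levels = tuple(pd.unique(g))
    lookup = {lev: i for i, lev in enumerate(levels)}
    try:
        codes = np.array([lookup[x] for x in g], dtype=int)
    except KeyError as e:
        raise ValueError(f"group label {e} not in levels {levels}") from None
    return codes, tuple(levels)


def fit_2pl_multigroup(
    rm,
    group,
    dif_items,
    grid: QuadratureGrid = QuadratureGrid(),
    tol: float = 1e-4,
    max_iter: int = 500,
    min_group_size: int = 30,
    levels=None,
) -> ItemParameters:
    """Multi-group 2PL with group-specific parameters for the DIF items.

    ``dif_items`` are 1-based item indices.  Anchor items are constrained
    equal across groups; the reference group (first level) prior is fixed to
    N(0, 1) and focal-group prior moments are estimated.  An empty DIF set is
    the fully constrained model, i.e. exactly the pooled single-group fit.
    """
    Y = _as_matrix(rm)
    ids = _item_ids(rm, Y.shape[1])
    k = Y.shape[1]
    dif = frozenset(int(i) for i in dif_items)
    if not dif <= set(range(1, k + 1)):
        raise ValueError(f"dif_items {sorted(dif)} outside 1..{k}")
    codes, levels = _group_codes(group, levels)
    if len(levels) < 2:
        raise ValueError("need at least two group levels")
    counts = np.bincount(codes, minlength=len(levels))
    small = [str(levels[i]) for i in range(len(levels)) if counts[i] < min_group_size]
    if small:
        raise InsufficientDataError(
            f"group levels below the size floor ({min_group_size}): {small}"
        )
    if len(dif) == k:
        raise NoAnchorError("every item is flagged; no anchor remains to link groups")

    if not dif:
        pooled = fit_2pl(rm, grid=grid, tol=tol, max_iter=max_iter)
        group_a = {lev: pooled.a.copy() for lev in levels}
        group_b = {lev: pooled.b.copy() for lev in levels}
        prior_mean = {lev: 0.0 for lev in levels}
        prior_sd = {lev: 1.0 for lev in levels}
        return ItemParameters(
            item_ids=ids,
            a=pooled.a,
            b=pooled.b,
            grid=grid,
            dif_items=dif,
            group_levels=levels,
            group_a=group_a,
            group_b=group_b,
            prior_mean=prior_mean,
            prior_sd=prior_sd,
            log_likelihood=pooled.log_likelihood,
            n_cycles=pooled.n_cycles,
            converged=pooled.converged,
            low_discrimination_items=pooled.low_discrimination_items,
        )

    _check_degenerate(Y, ids)
    M = (~np.isnan(Y)).astype(float)
    Y0 = np.nan_to_num(Y)
    nodes = grid.nodes
    G = len(levels)
    dif0 = np.array(sorted(i - 1 for i in dif))  # 0-based
    anchor0 = np.array([j for j in range(k) if j + 1 not in dif])

    a0, c0 = _start_values(Y)
    A = np.tile(a0, (G, 1))  # (G, k) slopes per group
    C = np.tile(c0, (G, 1))
    mu = np.zeros(G)
    sd = np.ones(G)
    rows = [np.flatnonzero(codes == g) for g in range(G)]

    prev_ll = -np.inf
    converged = False
    cycles = 0
    for cycles in range(1, max_iter + 1):
        ll = 0.0
        R = np.zeros((G, k, grid.n_nodes))
        N = np.zeros((G, k, grid.n_nodes))
        post_mean = np.zeros(G)
        post_var = np.zeros(G)
        for g in range(G):
            idx = rows[g]
            log_w = np.log(grid.weights(mu[g], sd[g]))
            post, mll = _posterior(Y0[idx], M[idx], A[g], C[g], nodes, log_w)
            ll += mll
            R[g] = (Y0[idx] * M[idx]).T @ post
            N[g] = M[idx].T @ post
            w_tot = post.sum(axis=0)
            nm = float(w_tot.sum())
            post_mean[g] = float(w_tot @ nodes) / nm
            post_var[g] = float(w_tot @ nodes**2) / nm - post_mean[g] ** 2
        if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased ({prev_ll} -> {ll}); optimizer failure"
            )
        prev_ll = ll

        newA, newC = A.copy(), C.copy()
        for j in anchor0:
            aj, cj = _mstep_item(nodes, R[:, j].sum(0), N[:, j].sum(0), A[0, j], C[0, j])
            newA[:, j] = aj
            newC[:, j] = cj
        for j in dif0:
            for g in range(G):
                newA[g, j], newC[g, j] = _mstep_item(nodes, R[g, j], N[g, j], A[g, j], C[g, j])
        new_mu = mu.copy()
        new_sd = sd.copy()
        for g in range(1, G):  # reference group stays N(0, 1)
            new_mu[g] = post_mean[g]
            new_sd[g] = float(np.sqrt(max(post_var[g], 1e-4)))
        delta = max(
            np.max(np.abs(newA - A)),
            np.max(np.abs(newC - C)),
            np.max(np.abs(new_mu - mu)),
            np.max(np.abs(new_sd - sd)),
        )
        A, C, mu, sd = newA, newC, new_mu, new_sd
        if delta < tol:
            converged = True
            break
    ll = 0.0
    for g in range(G):
        idx = rows[g]
        log_w = np.log(grid.weights(mu[g], sd[g]))
        _, mll = _posterior(Y0[idx], M[idx], A[g], C[g], nodes, log_w)
        ll += mll
    if not converged:
        warnings.warn(
            f"multigroup 2PL EM stopped after {cycles} cycles without reaching tol={tol}",
            ConvergenceWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.where(A != 0, -C / A, np.nan)
    shared_a, shared_b = A[0].copy(), B[0].copy()
    return ItemParameters(
        item_ids=ids,
        a=shared_a,
        b=shared_b,
        grid=grid,
        dif_items=dif,
        group_levels=levels,
        group_a={levels[g]: A[g].copy() for g in range(G)},
        group_b={levels[g]: B[g].copy() for g in range(G)},
        prior_mean={levels[g]: float(mu[g]) for g in range(G)},
        prior_sd={levels[g]: float(sd[g]) for g in range(G)},
        log_likelihood=ll,
        n_cycles=cycles,
        converged=converged,
    )


def eap_scores(rm, params: ItemParameters, group=None) -> AbilityEstimates:
    """EAP ability estimates under the fitted parameters and trait prior.

    When ``params`` carry group-specific entries a ``group`` label vector must
    be supplied so each person is scored with their own group's parameters and
    prior.  Persons with every item missing are excluded (NaN estimate, index
    recorded in ``excluded``).
    """
    Y = _as_matrix(rm)
    if Y.shape[1] != params.n_items:
        raise ValueError("response matrix and parameters disagree on item count")
    if params.multigroup and group is None:
        raise ValueError("group labels required to score with group-specific parameters")
    M = (~np.isnan(Y)).astype(float)
    Y0 = np.nan_to_num(Y)
    nodes = params.grid.nodes
    n = Y.shape[0]
    theta = np.full(n, np.nan)
    psd = np.full(n, np.nan)

    if params.multigroup and group is not None:
        codes, levels = _group_codes(group, params.group_levels)
        blocks = [(lev, np.flatnonzero(codes == i)) for i, lev in enumerate(levels)]
    else:
        blocks = [(None, np.arange(n))]
    for level, idx in blocks:
        if idx.size == 0:
            continue
        a, b = params.params_for(level)
        c = -a * b
        mean, sdv = params.prior_for(level)
        log_w = np.log(params.grid.weights(mean, sdv))
        post, _ = _posterior(Y0[idx], M[idx], a, c, nodes, log_w)
        m1 = post @ nodes
        m2 = post @ nodes**2
        theta[idx] = m1
        psd[idx] = np.sqrt(np.maximum(m2 - m1**2, 0.0))
    all_missing = np.flatnonzero(M.sum(axis=1) == 0)
    theta[all_missing] = np.nan
    psd[all_missing] = np.nan
    return AbilityEstimates(theta=theta, posterior_sd=psd, excluded=tuple(all_missing))


def item_curve(params: ItemParameters, item: int, theta_grid, group=None) -> np.ndarray:
    """Expected score of a single item (2PL probability) over a trait grid."""
    grid = np.asarray(theta_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0):
        raise ValueError("theta grid must be 1-d and sorted")
    a, b = params.params_for(group)
    j = int(item) - 1
    if not 0 <= j < params.n_items:
        raise ValueError(f"item {item} outside 1..{params.n_items}")
    return _sigmoid(a[j] * (grid - b[j]))


def tcc(params: ItemParameters, items, theta_grid, group=None) -> np.ndarray:
    """Test characteristic curve: summed expected score of ``items`` over the grid."""
    items = list(items)
    if not items:
        raise ValueError("empty item subset")
    grid = np.asarray(theta_grid, dtype=float)
    total = np.zeros_like(grid)
    for item in items:
        total += item_curve(params, item, grid, group)
    return total


class TwoParameterLogistic(BaseEstimator, TransformerMixin):
    """scikit-learn style estimator wrapping the 2PL MML calibration.

    ``fit(X)`` calibrates item parameters from an ``(n_persons, n_items)`` 0/1
    matrix (NaN = missing); pass ``group=`` labels plus ``dif_items=`` to run
    the multi-group calibration with group-specific DIF-item parameters.
    ``transform(X)`` returns EAP trait estimates as an ``(n, 1)`` column so the
    estimator composes with sklearn pipelines.

    Attributes
    ----------
    item_parameters_ : ItemParameters
    discrimination_, difficulty_ : (k,) arrays (shared/anchor values)
    log_likelihood_ : float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_quadrature: int = 49,
        theta_range=(-6.0, 6.0),
        tol: float = 1e-4,
        max_iter: int = 500,
        low_discrimination_floor: float = 0.2,
        min_group_size: int = 30,
    ):
        self.n_quadrature = n_quadrature
        self.theta_range = theta_range
        self.tol = tol
        self.max_iter = max_iter
        self.low_discrimination_floor = low_discrimination_floor
        self.min_group_size = min_group_size

    def _grid(self) -> QuadratureGrid:
        return QuadratureGrid(self.n_quadrature, *self.theta_range)

    def fit(self, X, y=None, *, group=None, dif_items=None):
        if group is not None and dif_items is not None:
            params = fit_2pl_multigroup(
                X,
                group,
                dif_items,
                grid=self._grid(),
                tol=self.tol,
                max_iter=self.max_iter,
                min_group_size=self.min_group_size,
            )
        else:
            params = fit_2pl(
                X,
                grid=self._grid(),
                tol=self.tol,
                max_iter=self.max_iter,
                low_discrimination_floor=self.low_discrimination_floor,
            )
        self.item_parameters_ = params
        self.discrimination_ = params.a
        self.difficulty_ = params.b
        self.log_likelihood_ = params.log_likelihood
        self.n_iter_ = params.n_cycles
        self.converged_ = params.converged
        return self

    def eap(self, X, group=None) -> AbilityEstimates:
        if not hasattr(self, "item_parameters_"):
            raise StateError("estimator is not fitted")
        return eap_scores(X, self.item_parameters_, group=group)

    def transform(self, X) -> np.ndarray:
        return self.eap(X).theta[:, None]
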