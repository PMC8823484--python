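"""Per-item logistic-regression DIF tests with likelihood-ratio statistics.

For each dichotomous item ``Y`` the probability of endorsement is modelled as
a function of the matching ability ``theta`` and a categorical group ``G``
through three nested binary logistic models

    M0:  logit P(Y=1) = b0 + b1*theta
    M1:  logit P(Y=1) = b0 + b1*theta + b2*G
    M2:  logit P(Y=1) = b0 + b1*theta + b2*G + b3*theta*G

Uniform DIF (a constant group effect at equal ability) corresponds to b2 != 0
with b3 = 0 and is tested by the G^2 likelihood-ratio statistic comparing M1
to M0; non-uniform DIF (a group-by-ability interaction) compares M2 to M1.
For an L-level group, b2 and b3 are blocks of L-1 dummy coefficients and the
tests are joint block tests with L-1 degrees of freedom.

Three magnitude measures accompany the tests:

* ``dbeta1`` -- the Crane/van Belle/Larson criterion
  ``|(b1_M0 - b1_M1) / b1_M0|``, the relative change of the ability slope when
  the group main effect enters;
* ``dR1 = 1 - lnL(M1)/lnL(M0)`` and ``dR2 = 1 - lnL(M2)/lnL(M1)``,
  log-likelihood-ratio pseudo-R^2 gains for the group and interaction terms.

Effects are classified "large" above 0.01 (dbeta1) and 0.07 (dR1, dR2) by
default; statistical flags use alpha = 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._optim import newton_logistic
from .exceptions import DesignError, SeparationError
from .scale import ResponseMatrix

__all__ = [
    "GroupFactor",
    "LogisticFit",
    "DIFItemResult",
    "DIFConfig",
    "fit_logistic",
    "effect_sizes",
    "dif_test_item",
    "dif_scan",
    "DIFScanner",
]


@dataclass(frozen=True)
class GroupFactor:
    """Categorical covariate with ordered levels; the first level is the reference."""

    levels: tuple
    codes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "codes", np.asarray(self.codes, dtype=int))
        if len(self.levels) < 2:
            raise ValueError("a group factor needs at least two levels")
        if self.codes.min() < 0 or self.codes.max() >= len(self.levels):
            raise ValueError("codes outside the level range")
        counts = np.bincount(self.codes, minlength=len(self.levels))
        if np.any(counts == 0):
            empty = [self.levels[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"empty group levels: {empty}")

    @classmethod
    def from_labels(cls, labels, levels=None) -> "GroupFactor":
        labels = np.asarray(labels)
        if levels is None:
            levels = tuple(pd.unique(labels))
        lookup = {lev: i for i, lev in enumerate(levels)}
        try:
            codes = np.array([lookup[x] for x in labels], dtype=int)
        except KeyError as e:
            raise ValueError(f"label {e} not among levels {levels}") from None
        return cls(tuple(levels), codes)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.levels, dtype=object)[self.codes]

    def dummies(self) -> np.ndarray:
        """(n, L-1) reference-coded indicator matrix."""
        n = len(self.codes)
        D = np.zeros((n, self.n_levels - 1))
        for lvl in range(1, self.n_levels):
            D[self.codes == lvl, lvl - 1] = 1.0
        return D

    def subset(self, mask) -> "GroupFactor":
        return GroupFactor(self.levels, self.codes[np.asarray(mask)])


@dataclass
class LogisticFit:
    """A converged binary-logistic ML fit."""

    coef: np.ndarray
    loglik: float
    grad_norm: float
    n_iter: int
    penalized: bool = False


def fit_logistic(
    y,
    X,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
    coef_bound: float = 40.0,
) -> LogisticFit:
    """Newton-Raphson ML fit of a binary logistic regression.

    Raises :class:`DesignError` on rank-deficient designs or constant ``y``,
    and :class:`SeparationError` (naming the runaway column) when the ML
    estimate diverges under quasi-complete separation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DesignError("design matrix and response are not conformable")
    if y.min() == y.max():
        raise DesignError("response is constant; the model is not identified")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    res = newton_logistic(X, y, tol=tol, max_iter=max_iter, ridge=ridge)
    if not res.converged or np.max(np.abs(res.coef)) > coef_bound:
        col = int(np.argmax(np.abs(res.coef)))
        raise SeparationError(col)
    return LogisticFit(res.coef, res.loglik, res.grad_norm, res.n_iter, ridge > 0)


@dataclass
class DIFItemResult:
    """Per-item DIF test outcome (one row of a Tables-2/3-style report)."""

    item: int
    item_id: str
    chi2_uniform: float = np.nan
    df_uniform: int = 0
    p_uniform: float = np.nan
    chi2_nonuniform: float = np.nan
    df_nonuniform: int = 0
    p_nonuniform: float = np.nan
    dbeta1: float | None = None
    dR1: float = np.nan
    dR2: float = np.nan
    flag_uniform: bool = False
    flag_nonuniform: bool = False
    large_dbeta1: bool = False
    large_dR1: bool = False
    large_dR2: bool = False
    penalized: bool = False
    status: str = "ok"
    reason: str = ""
    fits: dict = field(default_factory=dict, repr=False)

    @property
    def flagged(self) -> bool:
        return self.flag_uniform or self.flag_nonuniform

    def to_row(self) -> dict:
        return {
            "item": self.item,
            "item_id": self.item_id,
            "chi2_nonuniform": self.chi2_nonuniform,
            "p_nonuniform": self.p_nonuniform,
            "dR2": self.dR2,
            "chi2_uniform": self.chi2_uniform,
            "p_uniform": self.p_uniform,
            "dR1": self.dR1,
            "dbeta1": np.nan if self.dbeta1 is None else self.dbeta1,
            "flag_uniform": self.flag_uniform,
            "flag_nonuniform": self.flag_nonuniform,
            "large_dbeta1": self.large_dbeta1,
            "large_dR1": self.large_dR1,
            "large_dR2": self.large_dR2,
            "penalized": self.penalized,
            "status": self.status,
        }


@dataclass(frozen=True)
class DIFConfig:
    """Test level and largeness thresholds for the DIF scan."""

    alpha: float = 0.01
    threshold_dbeta1: float = 0.01
    threshold_dR1: float = 0.07
    threshold_dR2: float = 0.07
    bonferroni: bool = False
    separation_ridge: float = 1e-6

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if min(self.threshold_dbeta1, self.threshold_dR1, self.threshold_dR2) <= 0:
            raise ValueError("effect-size thresholds must be positive")


def effect_sizes(fit_m0: LogisticFit, fit_m1: LogisticFit, fit_m2: LogisticFit):
    """(dbeta1, dR1, dR2) from the three nested fits.

    ``dbeta1 = |(b1_M0 - b1_M1)/b1_M0|`` where b1 is the ability slope
    (coefficient of theta, column 1 in all three designs);
    ``dR1 = 1 - lnL(M1)/lnL(M0)``; ``dR2 = 1 - lnL(M2)/lnL(M1)``.
    ``dbeta1`` is None (not available) when b1_M0 = 0.
    """
    b1_m0 = fit_m0.coef[1]
    b1_m1 = fit_m1.coef[1]
    if b1_m0 == 0:
        warnings.warn("ability slope in the baseline model is 0; dbeta1 undefined")
        dbeta1 = None
    else:
        dbeta1 = abs((b1_m0 - b1_m1) / b1_m0)
    dR1 = 1.0 - fit_m1.loglik / fit_m0.loglik if fit_m0.loglik != 0 else 0.0
    dR2 = 1.0 - fit_m2.loglik / fit_m1.loglik if fit_m1.loglik != 0 else 0.0
    return dbeta1, dR1, dR2


def _fit_with_fallback(y, X, ridge_fallback):
    try:
        return fit_logistic(y, X), False
    except SeparationError:
        res = newton_logistic(X, y, tol=1e-8, max_iter=200, ridge=ridge_fallback)
        return LogisticFit(res.coef, res.loglik, res.grad_norm, res.n_iter, True), True


def dif_test_item(
    y,
    theta,
    g: GroupFactor,
    config: DIFConfig = DIFConfig(),
    item: int = 1,
    item_id: str | None = None,
    n_tests: int = 1,
) -> DIFItemResult:
    """Run the nested-model likelihood-ratio DIF test for one item.

    Rows with a missing response or non-finite ability are dropped listwise.
    On separation the affected fits are refit with a small ridge penalty and
    the result is marked ``penalized``; on any other failure the item is
    returned with status ``untestable`` and the scan can continue.
    """
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    keep = ~np.isnan(y) & np.isfinite(theta)
    y, theta = y[keep], theta[keep]
    gk = g.subset(keep)
    item_id = item_id or f"item_{item}"
    result = DIFItemResult(item=item, item_id=item_id)

    D = gk.dummies()
    X0 = np.column_stack([np.ones_like(theta), theta])
    X1 = np.column_stack([X0, D])
    X2 = np.column_stack([X1, theta[:, None] * D])
    try:
        f0, p0 = _fit_with_fallback(y, X0, config.separation_ridge)
        f1, p1 = _fit_with_fallback(y, X1, config.separation_ridge)
        f2, p2 = _fit_with_fallback(y, X2, config.separation_ridge)
    except (DesignError, np.linalg.LinAlgError) as e:
        result.status = "untestable"
        result.reason = str(e)
        return result

    df = gk.n_levels - 1
    chi2_u = max(2.0 * (f1.loglik - f0.loglik), 0.0)
    chi2_n = max(2.0 * (f2.loglik - f1.loglik), 0.0)
    alpha = config.alpha / n_tests if config.bonferroni else config.alpha
    dbeta1, dR1, dR2 = effect_sizes(f0, f1, f2)

    result.chi2_uniform = chi2_u
    result.df_uniform = df
    result.p_uniform = float(stats.chi2.sf(chi2_u, df))
    result.chi2_nonuniform = chi2_n
    result.df_nonuniform = df
    result.p_nonuniform = float(stats.chi2.sf(chi2_n, df))
    result.dbeta1 = dbeta1
    result.dR1 = dR1
    result.dR2 = dR2
    result.flag_uniform = result.p_uniform <= alpha
    result.flag_nonuniform = result.p_nonuniform <= alpha
    result.large_dbeta1 = dbeta1 is not None and dbeta1 > config.threshold_dbeta1
    result.large_dR1 = dR1 > config.threshold_dR1
    result.large_dR2 = dR2 > config.threshold_dR2
    result.penalized = p0 or p1 or p2
    result.fits = {"m0": f0, "m1": f1, "m2": f2}
    return result


def dif_scan(rm, theta, g: GroupFactor, config: DIFConfig = DIFConfig()):
    """DIF-test every item of the matrix; returns a list of DIFItemResult."""
    Y = rm.values if isinstance(rm, ResponseMatrix) else np.asarray(rm, dtype=float)
    ids = (
        rm.item_ids
        if isinstance(rm, ResponseMatrix)
        else [f"item_{j}" for j in range(1, Y.shape[1] + 1)]
    )
    k = Y.shape[1]
    return [
        dif_test_item(
            Y[:, j], theta, g, config, item=j + 1, item_id=str(ids[j]), n_tests=k
        )
        for j in range(k)
    ]


def results_frame(results) -> pd.DataFrame:
    """Tabulate scan results in the layout of a published DIF table."""
    return pd.DataFrame([r.to_row() for r in results]).set_index("item")


class DIFScanner(BaseEstimator):
    """scikit-learn style wrapper around the per-item DIF scan.

    ``fit(X, y)`` takes the scored response matrix ``X`` and group labels
    ``y``; the matching ability is passed as ``theta=`` (it usually comes from
    a :class:`~difkit.irt.TwoParameterLogistic` transform).

    Attributes
    ----------
    results_ : list of DIFItemResult
    table_ : pandas.DataFrame
    flagged_items_, uniform_items_, nonuniform_items_ : sorted 1-based indices
    """

    def __init__(
        self,
        alpha: float = 0.01,
        threshold_dbeta1: float = 0.01,
        threshold_dR1: float = 0.07,
        threshold_dR2: float = 0.07,
        bonferroni: bool = False,
    ):
        self.alpha = alpha
        self.threshold_dbeta1 = threshold_dbeta1
        self.threshold_dR1 = threshold_dR1
        self.threshold_dR2 = threshold_dR2
        self.bonferroni = bonferroni

    def _config(self) -> DIFConfig:
        return DIFConfig(
            alpha=self.alpha,
            threshold_dbeta1=self.threshold_dbeta1,
            threshold_dR1=self.threshold_dR1,
            threshold_dR2=self.threshold_dR2,
            bonferroni=self.bonferroni,
        )

    def fit(self, X, y, *, theta):
        g = y if isinstance(y, GroupFactor) else GroupFactor.from_labels(y)
        theta = np.asarray(theta, dtype=float).reshape(-1)
        self.results_ = dif_scan(X, theta, g, self._config())
        self.table_ = results_frame(self.results_)
        self.uniform_items_ = sorted(r.item for r in self.results_ if r.flag_uniform)
        self.nonuniform_items_ = sorted(r.item for r in self.results_ if r.flag_nonuniform)
        self.flagged_items_ = sorted(r.item for r in self.results_ if r.flagged)
        return self
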