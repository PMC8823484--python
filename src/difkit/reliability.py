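"""Internal-consistency and one-factor fit indices for dichotomous scales.

Provides Cronbach's alpha on the 0/1 scored items, pairwise tetrachoric
correlations (the latent bivariate-normal correlations implied by each 2x2
table), and a single-factor model fitted to the tetrachoric matrix by
unweighted least squares (ULS).  From the factor solution come McDonald's
omega-total and the usual structural fit indices -- SRMR from the residual
correlations, and RMSEA/CFI/TLI from the ML discrepancy of the fitted versus
observed matrix against an independence baseline -- each flagged against
Hu-Bentler-style cutoffs (SRMR <= .08, RMSEA <= .06, CFI >= .95, TLI >= .95 by
default).

Binary-item caveat: the chi-square-based indices treat the tetrachoric matrix
as if it were an ordinary covariance matrix of n observations, which is the
common pragmatic approximation when the estimator behind published values is
unstated; SRMR and omega do not depend on that approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import StateError
from .scale import ResponseMatrix

__all__ = [
    "HuBentlerCutoffs",
    "OneFactorFit",
    "cronbach_alpha",
    "tetrachoric_pair",
    "tetrachoric_matrix",
    "one_factor_fit",
    "reliability_report",
]


def _values(rm) -> np.ndarray:
    if isinstance(rm, ResponseMatrix):
        if not rm.scored:
            raise StateError("reliability indices require a scored matrix")
        return rm.values
    return np.asarray(rm, dtype=float)


def _complete(X: np.ndarray) -> np.ndarray:
    return X[~np.isnan(X).any(axis=1)]


def cronbach_alpha(rm) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/variance(total)).

    Computed on complete cases; NaN (with a warning) when the total score has
    zero variance.
    """
    X = _complete(_values(rm))
    n, k = X.shape
    if k < 2:
        raise ValueError("alpha needs at least two items")
    if n < 2:
        raise ValueError("alpha needs at least two complete cases")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        warnings.warn("total score has zero variance; alpha undefined")
        return float("nan")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def _bvn_cdf(t1: float, t2: float, rho: float) -> float:
    cov = [[1.0, rho], [rho, 1.0]]
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([t1, t2]))


def tetrachoric_pair(x, y, continuity: float = 0.5):
    """Tetrachoric correlation of two 0/1 vectors (pairwise complete).

    Thresholds come from the marginal endorsement rates; the correlation is
    the rho under which the bivariate-normal quadrant probability matches the
    observed (0,0) cell.  Empty cells get a continuity correction of
    ``continuity`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n == 0:
        raise ValueError("no pairwise-complete observations")
    n11 = float(np.sum((x == 1) & (y == 1)))
    n10 = float(np.sum((x == 1) & (y == 0)))
    n01 = float(np.sum((x == 0) & (y == 1)))
    n00 = float(np.sum((x == 0) & (y == 0)))
    if min(n11, n10, n01, n00) == 0:
        warnings.warn("empty 2x2 cell; applying continuity correction")
        n11 += continuity
        n10 += continuity
        n01 += continuity
        n00 += continuity
    total = n11 + n10 + n01 + n00
    px = (n11 + n10) / total  # P(x = 1)
    py = (n11 + n01) / total
    if not (0 < px < 1 and 0 < py < 1):
        raise ValueError("degenerate margin; tetrachoric undefined")
    t1 = stats.norm.ppf(1.0 - px)  # x = 1 when the latent exceeds t1
    t2 = stats.norm.ppf(1.0 - py)
    p00 = n00 / total

    def f(rho):
        return _bvn_cdf(t1, t2, rho) - p00

    lo, hi = -0.9999, 0.9999
    flo, fhi = f(lo), f(hi)
    if flo >= 0:
        return -1.0
    if fhi <= 0:
        return 1.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


def _nearest_psd(R: np.ndarray, eig_floor: float = 1e-6):
    """Floor the eigenvalues and rescale to unit diagonal; returns (R, repaired)."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= eig_floor:
        return R, False
    vals = np.maximum(vals, eig_floor)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def tetrachoric_matrix(rm, eig_floor: float = 1e-6) -> np.ndarray:
    """Pairwise tetrachoric correlation matrix, repaired to PSD if needed."""
    X = _values(rm)
    k = X.shape[1]
    R = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            R[i, j] = R[j, i] = tetrachoric_pair(X[:, i], X[:, j])
    R, repaired = _nearest_psd(R, eig_floor)
    if repaired:
        warnings.warn("tetrachoric matrix was not PSD; eigenvalues floored")
    return R


@dataclass
class HuBentlerCutoffs:
    """Acceptability cutoffs for the fit indices (flag = out of range)."""

    srmr_max: float = 0.08
    rmsea_max: float = 0.06
    cfi_min: float = 0.95
    tli_min: float = 0.95

    def flags(self, rmsea, srmr, cfi, tli) -> dict:
        return {
            "rmsea": bool(rmsea > self.rmsea_max),
            "srmr": bool(srmr > self.srmr_max),
            "cfi": bool(cfi < self.cfi_min),
            "tli": bool(tli < self.tli_min),
        }


@dataclass
class OneFactorFit:
    """ULS single-factor solution with reliability and fit indices."""

    loadings: np.ndarray
    omega: float
    rmsea: float
    srmr: float
    cfi: float
    tli: float
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    heywood: bool
    flags: dict = field(default_factory=dict)

    @property
    def residuals(self) -> np.ndarray:
        return self._residuals

    @residuals.setter
    def residuals(self, value):
        self._residuals = value


def one_factor_fit(
    R: np.ndarray, n: int, cutoffs: HuBentlerCutoffs = HuBentlerCutoffs()
) -> OneFactorFit:
    """Fit a single-factor model to a correlation matrix by ULS.

    Minimizes the sum of squared off-diagonal residuals of
    ``R - loadings @ loadings.T``.  omega-total is
    ``(sum lam)^2 / ((sum lam)^2 + sum(1 - lam^2))``; SRMR is the root mean
    square of the off-diagonal residual correlations.  RMSEA, CFI and TLI are
    derived from the ML discrepancy of the fitted model evaluated at the ULS
    solution against the independence baseline.  Heywood loadings (|lam| > 1)
    are clipped and flagged.
    """
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    if R.shape != (k, k) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be a symmetric correlation matrix")
    if n <= k:
        raise ValueError("need more observations than items")
    off = ~np.eye(k, dtype=bool)

    vals, vecs = np.linalg.eigh(R)
    lam0 = vecs[:, -1] * np.sqrt(max(vals[-1], 1e-8))
    if lam0.sum() < 0:
        lam0 = -lam0

    def objective(lam):
        res = (R - np.outer(lam, lam))[off]
        return 0.5 * float(res @ res)

    def gradient(lam):
        res = R - np.outer(lam, lam)
        np.fill_diagonal(res, 0.0)
        return -2.0 * res @ lam

    sol = optimize.minimize(objective, lam0, jac=gradient, method="L-BFGS-B")
    lam = sol.x
    if lam.sum() < 0:
        lam = -lam
    heywood = bool(np.any(np.abs(lam) > 1.0 + 1e-8))
    if heywood:
        warnings.warn("Heywood case: loadings clipped to |1|")
    lam = np.clip(lam, -1.0, 1.0)

    resid = R - np.outer(lam, lam)
    np.fill_diagonal(resid, 0.0)
    srmr = float(np.sqrt(np.mean(resid[off] ** 2)))
    s = lam.sum()
    omega = float(s**2 / (s**2 + np.sum(1.0 - lam**2)))

    sigma = np.outer(lam, lam)
    np.fill_diagonal(sigma, 1.0)
    df = k * (k - 1) // 2 - k
    df_b = k * (k - 1) // 2
    sign_S, logdet_S = np.linalg.slogdet(R)
    sign_M, logdet_M = np.linalg.slogdet(sigma)
    if sign_S <= 0 or sign_M <= 0:
        # singular input (e.g. perfectly consistent items): the ML discrepancy
        # is undefined, but omega and SRMR above remain meaningful
        warnings.warn("singular correlation matrix; chi-square indices undefined")
        chi2 = chi2_b = rmsea = cfi = tli = float("nan")
    else:
        f_model = float(logdet_M - logdet_S + np.trace(R @ np.linalg.inv(sigma)) - k)
        f_base = float(-logdet_S)  # independence model: Sigma = I, trace term = k
        chi2 = (n - 1) * max(f_model, 0.0)
        chi2_b = (n - 1) * max(f_base, 0.0)
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 else float("nan")
        denom = max(chi2_b - df_b, chi2 - df, 0.0)
        cfi = 1.0 if denom == 0 else float(1.0 - max(chi2 - df, 0.0) / denom)
        if df > 0 and df_b > 0 and chi2_b / df_b > 1.0:
            tli = float(((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0))
        else:
            tli = float("nan")

    fit = OneFactorFit(
        loadings=lam,
        omega=omega,
        rmsea=rmsea,
        srmr=srmr,
        cfi=cfi,
        tli=tli,
        chi2=float(chi2),
        df=df,
        chi2_baseline=float(chi2_b),
        df_baseline=df_b,
        heywood=heywood,
        flags=cutoffs.flags(rmsea, srmr, cfi, tli),
    )
    fit.residuals = resid
    return fit


def reliability_report(
    rm, group=None, cutoffs: HuBentlerCutoffs = HuBentlerCutoffs()
) -> pd.DataFrame:
    """Alpha, omega and fit indices per subgroup plus the total sample.

    One row per group level (when ``group`` labels are given) and a ``total``
    row, mirroring a per-factor reliability table.  Out-of-range values are
    flagged in the ``*_flag`` columns.
    """
    X = _complete(_values(rm))
    if group is not None:
        group = np.asarray(group)
        if len(group) != X.shape[0]:
            raise ValueError("group labels must align with complete cases")
    rows = []

    def one(sub_X, label):
        alpha = cronbach_alpha(sub_X)
        R = tetrachoric_matrix(sub_X)
        fit = one_factor_fit(R, sub_X.shape[0], cutoffs)
        rows.append(
            {
                "subgroup": label,
                "n": sub_X.shape[0],
                "alpha": alpha,
                "omega": fit.omega,
                "rmsea": fit.rmsea,
                "srmr": fit.srmr,
                "cfi": fit.cfi,
                "tli": fit.tli,
                "rmsea_flag": fit.flags["rmsea"],
                "srmr_flag": fit.flags["srmr"],
                "cfi_flag": fit.flags["cfi"],
                "tli_flag": fit.flags["tli"],
            }
        )

    if group is not None:
        for level in pd.unique(group):
            one(X[group == level], str(level))
    one(X, "total")
    return pd.DataFrame(rows).set_index("subgroup")
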