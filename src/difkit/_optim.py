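"""Newton-Raphson solver for (weighted) binomial logistic likelihoods.

Shared by the per-item DIF regressions (unit trials) and the EM M-step of the
2PL calibration (fractional expected counts at quadrature nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NewtonResult", "newton_logistic", "binomial_loglik"]


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def binomial_loglik(coef, X, successes, trials, ridge=0.0):
    """Binomial log-likelihood sum(s*log p + (t-s)*log(1-p)) minus ridge penalty."""
    eta = X @ coef
    # log p and log(1-p) via stable softplus
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    ll = float(np.sum(successes * log_p + (trials - successes) * log_q))
    if ridge:
        ll -= 0.5 * ridge * float(coef @ coef)
    return ll


@dataclass
class NewtonResult:
    coef: np.ndarray
    loglik: float
    grad_norm: float
    converged: bool
    n_iter: int


def newton_logistic(
    X,
    successes,
    trials=None,
    coef0=None,
    tol=1e-8,
    max_iter=100,
    ridge=0.0,
) -> NewtonResult:
    """Maximize the binomial logistic likelihood by damped Newton-Raphson.

    Parameters
    ----------
    X : (m, d) design matrix.
    successes : (m,) success counts (0/1 responses when ``trials`` is None).
    trials : (m,) trial counts; defaults to ones.
    coef0 : starting coefficients; defaults to zeros.
    tol : max-norm of the score vector at which the fit is declared converged.
    ridge : optional L2 penalty used to stabilize separated fits.

    Step-halving guarantees the (penalized) log-likelihood never decreases.
    """
    X = np.asarray(X, dtype=float)
    s = np.asarray(successes, dtype=float)
    t = np.ones_like(s) if trials is None else np.asarray(trials, dtype=float)
    m, d = X.shape
    coef = np.zeros(d) if coef0 is None else np.asarray(coef0, dtype=float).copy()

    ll = binomial_loglik(coef, X, s, t, ridge)
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        p = _sigmoid(X @ coef)
        grad = X.T @ (s - t * p)
        if ridge:
            grad -= ridge * coef
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < tol:
            return NewtonResult(coef, ll, grad_norm, True, it - 1)
        w = t * p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        if ridge:
            H += ridge * np.eye(d)
        # fall back to gradient direction if the Hessian is numerically singular
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / max(1.0, float(np.max(np.abs(w))) * m)
        scale = 1.0
        for _ in range(40):
            new = coef + scale * step
            new_ll = binomial_loglik(new, X, s, t, ridge)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        else:  # pragma: no cover - step-halving exhausted
            return NewtonResult(coef, ll, grad_norm, False, it)
        coef, ll = new, new_ll
    p = _sigmoid(X @ coef)
    grad = X.T @ (s - t * p)
    if ridge:
        grad -= ridge * coef
    grad_norm = float(np.max(np.abs(grad)))
    return NewtonResult(coef, ll, grad_norm, grad_norm < tol, it)
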