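"""Minimal IRLS logistic fit shared by the score tests and kernel tests."""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_MU_EPS = 1e-10
_COEF_BOUND = 30.0  # |log-odds| beyond this signals (quasi-)separation


class ConvergenceError(RuntimeError):
    """The null logistic fit failed to converge."""


class SeparationError(ConvergenceError):
    """Perfect or quasi-perfect separation; a penalized fit is advised."""


def irls_logistic(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit logit(P(y=1)) = X beta by iteratively reweighted least squares.

    Converges when the relative log-likelihood change drops below ``tol``.
    Returns ``(beta, mu)``.  Raises :class:`SeparationError` when the
    coefficients diverge (fitted probabilities pinned at 0/1).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError("response is constant; null model undefined")
    beta = np.zeros(q)
    ll_old = -np.inf
    for _ in range(maxiter):
        eta = X @ beta
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        w = mu * (1.0 - mu)
        # Newton step on the log-likelihood
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix in IRLS: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > _COEF_BOUND:
            raise SeparationError(
                "coefficients diverging (|beta| > 30): data are separated; "
                "use a penalized logistic fit"
            )
        eta = X @ beta
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        ll = float(y @ np.log(mu) + (1.0 - y) @ np.log1p(-mu))
        if abs(ll - ll_old) <= tol * (abs(ll) + 1.0):
            return beta, mu
        ll_old = ll
    raise ConvergenceError(f"IRLS did not converge in {maxiter} iterations")
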