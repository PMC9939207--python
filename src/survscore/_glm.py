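"""Minimal Newton-Raphson binary logistic regression used by the propensity
model and the calibration recalibration step."""

from __future__ import annotations

import numpy as np

from .errors import EstimationError


def fit_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logit fit; ``X`` must already include an intercept
    column.  Returns (beta, fitted probabilities, converged flag)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if set(np.unique(y).tolist()) != {0.0, 1.0}:
        raise EstimationError("outcome must contain both classes, coded 0/1")
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta += delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e3:
            break  # separation: diverging coefficients
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    return beta, mu, converged
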