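"""Small Newton–Raphson logistic solvers used inside bootstrap loops.

statsmodels handles the user-facing model fits (standard errors,
summaries); these routines exist because percentile-bootstrap and
parameter-recovery procedures refit the same small logistic design
thousands of times, where a vectorised batched Newton solve is orders of
magnitude faster than constructing a statsmodels model per resample.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bernoulli_loglik(y: np.ndarray, p: np.ndarray, axis=-1) -> np.ndarray:
    """Sum of Bernoulli log-likelihoods with probabilities clipped away from 0/1."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.sum(y * np.log(p) + (1 - y) * np.log1p(-p), axis=axis)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, bool]:
    """ML logistic fit; returns (beta, log-likelihood, converged).

    ``ridge`` adds an L2 penalty (not counted in the returned
    log-likelihood) to stabilise separated designs.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = sigmoid(eta)
        w = mu * (1 - mu) + 1e-12
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X * w[:, None]).T @ X + (ridge + 1e-12) * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # dampen runaway steps on near-separated data
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    llf = bernoulli_loglik(y, sigmoid(X @ beta))
    return beta, float(llf), converged


def fit_logistic_batched(
    Xb: np.ndarray,
    yb: np.ndarray,
    ridge: float = 1e-8,
    max_iter: int = 50,
    tol: float = 1e-8,
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    """Fit B independent logistic regressions at once.

    Xb has shape (B, n, p); yb has shape (B, n).  Returns betas of
    shape (B, p).  A tiny ridge keeps occasional separated resamples
    finite; the damping cap mirrors :func:`fit_logistic`.  ``beta0``
    warm-starts all batches (e.g. at the full-data estimate when the
    batches are bootstrap resamples).
    """
    Xb = np.asarray(Xb, float)
    yb = np.asarray(yb, float)
    B, n, p = Xb.shape
    betas = np.zeros((B, p)) if beta0 is None else np.tile(np.asarray(beta0, float), (B, 1))
    eye = np.eye(p)
    for _ in range(max_iter):
        eta = np.einsum("bnp,bp->bn", Xb, betas)
        mu = sigmoid(eta)
        w = mu * (1 - mu) + 1e-12
        grad = np.einsum("bnp,bn->bp", Xb, yb - mu) - ridge * betas
        hess = np.einsum("bnp,bn,bnq->bpq", Xb, w, Xb) + (ridge + 1e-12) * eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        norm = np.max(np.abs(step), axis=1, keepdims=True)
        scale = np.where(norm > 10.0, 10.0 / norm, 1.0)
        betas = betas + step * scale
        if np.max(np.abs(step)) < tol:
            break
    return betas
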