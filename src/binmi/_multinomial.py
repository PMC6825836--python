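"""Ridge-penalized multinomial logistic regression, batched over designs.

This is the numerical workhorse behind polytomous imputation and the
forward-stepwise BIC selection.  A single Newton solver handles a stack
of B design matrices at once — the per-site and per-candidate paths
batch thousands of small fits into a handful of BLAS calls, which is
what makes the separate-sites strategy tractable on one CPU.

Conventions: class 0 is the reference; coefficients have shape
``(B, K-1, p)``; column 0 of each design is assumed to be the intercept
and is excluded from the ridge penalty.  Under (near-)separation the
penalized optimum has very large but finite coefficients; Newton steps
are inf-norm capped so iterates drift there stably, and fitted
probabilities (all the imputation uses) converge long before the
coefficients do.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_multinomial", "predict_proba", "loglik"]


def _as_batch(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 2:
        X = X[None]
    if y.ndim == 1:
        y = np.broadcast_to(y, (X.shape[0], y.shape[0]))
    return X, y


def _probs(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Class probabilities for classes 1..K-1 (reference prob is the remainder)."""
    eta = np.matmul(X, beta.transpose(0, 2, 1))  # (B, n, K-1)
    mx = np.maximum(eta.max(axis=-1), 0.0)  # guard overflow; ref class has eta 0
    z = np.exp(eta - mx[..., None])
    denom = np.exp(-mx) + z.sum(axis=-1)
    return z / denom[..., None]


def fit_multinomial(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    ridge: float = 1e-5,
    max_iter: int = 25,
    tol: float = 1e-6,
    max_step: float = 4.0,
) -> np.ndarray:
    """Fit multinomial logistic models by penalized Newton iteration.

    Parameters
    ----------
    X
        Design matrices, shape ``(n, p)`` or ``(B, n, p)``; column 0 is
        the intercept.
    y
        Integer class codes in ``[0, n_classes)``, shape ``(n,)`` or
        ``(B, n)``.  A 1-D ``y`` is shared across the batch.
    n_classes
        Number of classes K (>= 2); class 0 is the reference.
    ridge
        Penalty 0.5 * ridge * n * ||beta||^2 on non-intercept
        coefficients; the default is small enough to leave well-posed
        fits at the MLE while keeping separated fits finite.
    tol
        Convergence on the max absolute penalized score, scaled by n.

    Returns
    -------
    Coefficients with shape ``(K-1, p)`` (unbatched input) or
    ``(B, K-1, p)``.
    """
    single = np.asarray(X).ndim == 2
    X, y = _as_batch(X, y)
    B, n, p = X.shape
    km = n_classes - 1
    if km < 1:
        raise ValueError("need at least two classes")
    q = km * p

    # one-hot for classes 1..K-1
    Y = np.zeros((B, n, km))
    for k in range(1, n_classes):
        Y[..., k - 1] = y == k

    pen = ridge * n
    pen_vec = np.full(p, pen)
    pen_vec[0] = 1e-10 * n  # tiny jitter keeps the intercept block invertible
    pen_diag = np.tile(pen_vec, km)

    beta = np.zeros((B, km, p))
    Xt = X.transpose(0, 2, 1)
    active = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        P = _probs(X, beta)
        G = np.matmul(Xt, Y - P).transpose(0, 2, 1)  # (B, km, p)
        G -= pen_vec[None, None, :] * beta
        g = G.reshape(B, q)
        active = np.abs(g).max(axis=1) > tol * n
        if not active.any():
            break
        H = np.zeros((B, km, p, km, p))
        for k in range(km):
            for l in range(k, km):
                w = P[..., k] * ((1.0 if k == l else 0.0) - P[..., l])
                if k == l:
                    blk = np.matmul(Xt, X * w[..., None])
                else:
                    blk = np.matmul(Xt, X * w[..., None])
                H[:, k, :, l, :] = blk
                if l != k:
                    H[:, l, :, k, :] = blk
        Hm = H.reshape(B, q, q)
        Hm[:, np.arange(q), np.arange(q)] += pen_diag
        step = np.linalg.solve(Hm, g[..., None])[..., 0]
        # cap step size: robust under separation, inert near the optimum
        nrm = np.abs(step).max(axis=1)
        scale = np.minimum(1.0, max_step / np.maximum(nrm, 1e-300))
        beta += (step * scale[:, None]).reshape(B, km, p) * active[:, None, None]
    return beta[0] if single else beta


def predict_proba(X: np.ndarray, beta: np.ndarray, n_classes: int) -> np.ndarray:
    """Full class-probability matrix, shape ``(..., n, K)`` (class 0 first)."""
    single = np.asarray(X).ndim == 2
    X = np.asarray(X, dtype=float)
    if single:
        X, beta = X[None], np.asarray(beta)[None]
    p1 = _probs(X, beta)
    p0 = 1.0 - p1.sum(axis=-1, keepdims=True)
    out = np.concatenate([p0, p1], axis=-1)
    return out[0] if single else out


def loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray, n_classes: int) -> np.ndarray:
    """Unpenalized log-likelihood, shape ``()`` or ``(B,)``."""
    single = np.asarray(X).ndim == 2
    X, y = _as_batch(X, y)
    if single:
        beta = np.asarray(beta)[None]
    eta = np.matmul(X, beta.transpose(0, 2, 1))
    mx = np.maximum(eta.max(axis=-1), 0.0)
    lse = mx + np.log(np.exp(-mx) + np.exp(eta - mx[..., None]).sum(axis=-1))
    eta_full = np.concatenate([np.zeros(eta.shape[:-1] + (1,)), eta], axis=-1)
    picked = np.take_along_axis(eta_full, y[..., None].astype(int), axis=-1)[..., 0]
    ll = (picked - lse).sum(axis=-1)
    return ll[0] if single else ll
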