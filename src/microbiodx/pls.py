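"""Minimal NIPALS partial-least-squares engine.

Shared by the community PLS-DA ordination and the OPLS-DA metabolomics
model. Operates on already-scaled matrices; scaling policy belongs to the
callers.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def pls_components(X: np.ndarray, Y: np.ndarray, k: int,
                   max_iter: int = 500, tol: float = 1e-10):
    """Extract ``k`` PLS components from centered X (n x p) and Y (n x m).

    Returns ``(T, W, P, Q)``: X-scores, X-weights (unit norm, computed
    against the deflated X), X-loadings and Y-loadings, each with one
    column per component.
    """
    X = np.asarray(X, dtype=float).copy()
    Y = np.asarray(Y, dtype=float).copy()
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if k < 1:
        raise ValidationError("number of components must be >= 1")
    if k > min(n, p):
        raise ValidationError(f"cannot extract {k} components from {n}x{p} data")
    T = np.zeros((n, k))
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    Q = np.zeros((Y.shape[1], k))
    for a in range(k):
        u = Y[:, int(np.argmax(np.var(Y, axis=0)))]
        if not np.any(u):
            u = Y[:, 0] + 1e-12
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = X.T @ u
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                break
            w_new /= nrm
            t = X @ w_new
            q = Y.T @ t / (t @ t)
            u_new = Y @ q / (q @ q) if (q @ q) > 0 else t
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        else:
            w = w_new
        t = X @ w
        tt = t @ t
        if tt == 0:
            break
        pvec = X.T @ t / tt
        q = Y.T @ t / tt
        X -= np.outer(t, pvec)
        Y -= np.outer(t, q)
        T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, pvec, q
    return T, W, P, Q
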