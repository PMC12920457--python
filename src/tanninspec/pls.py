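"""NIPALS partial least squares regression (PLS1) on mean-centered data.

Latent variables are extracted sequentially: for a univariate response the
NIPALS weight update converges in a single step, so each component uses the
closed-form weight w = X'y / ||X'y|| followed by score/loading extraction
and deflation of X and y.  Regression coefficients are recovered as
B = W (P'W)^-1 q and applied to centered inputs.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = ["NipalsPLS", "pls_fit"]


class NipalsPLS(BaseEstimator, RegressorMixin):
    """PLS1 regression with NIPALS-style sequential latent variables.

    Parameters
    ----------
    n_components : int
        Requested number of latent variables; capped at
        ``min(n_train - 1, n_bands)`` with a logged warning if reduced.
    """

    def __init__(self, n_components=2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 training samples")
        if y.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        if np.ptp(y) == 0:
            raise ValueError("response y has zero variance")

        cap = min(n - 1, p)
        k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k > cap:
            logger.warning("n_components reduced from %d to %d (n=%d, p=%d)", k, cap, n, p)
            k = cap

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        W = np.zeros((p, k))
        P = np.zeros((p, k))
        q = np.zeros(k)
        n_used = 0
        for comp in range(k):
            w = Xc.T @ yc
            wn = np.linalg.norm(w)
            if wn < 1e-12 * max(1.0, np.abs(yc).max()):
                break  # residual response orthogonal to X: stop early
            w /= wn
            t = Xc @ w
            tt = t @ t
            if tt < 1e-30:
                break
            P[:, comp] = (Xc.T @ t) / tt
            q[comp] = (t @ yc) / tt
            W[:, comp] = w
            Xc = Xc - np.outer(t, P[:, comp])
            yc = yc - t * q[comp]
            n_used += 1

        W, P, q = W[:, :n_used], P[:, :n_used], q[:n_used]
        if n_used == 0:
            self.coef_ = np.zeros(p)
        else:
            self.coef_ = W @ np.linalg.solve(P.T @ W, q)
        self.n_components_ = n_used
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


def pls_fit(X, y, n_components: int) -> NipalsPLS:
    """Fit a mean-centered NIPALS PLS1 model (thin wrapper)."""
    return NipalsPLS(n_components=n_components).fit(X, y)
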