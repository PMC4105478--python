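"""Independent primal NIPALS PLS2 oracle used by the test suite.

Deliberately coded from the classical primal recursion — weight vectors in
gene space, score vectors from X w — and kept free of any import from the
package's component extractor, so that agreement between the two routes is
an actual cross-check.  Normalization conventions (unit t, unit u) mirror
the dual algorithm so scores are comparable up to sign.
"""

from __future__ import annotations

import numpy as np


def one_hot_centered(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    Y = np.zeros((labels.shape[0], len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y - Y.mean(axis=0, keepdims=True)


def primal_nipals(X, Y, n_components, tol=1e-12, max_iter=2000):
    """Classical NIPALS PLS2 on column-centered X and centered Y.

    Returns (T, W_raw) where T columns are unit score vectors and W_raw
    columns are the (unnormalized) gene weights X_h' u at convergence.
    """
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y = Y.copy()
    n = X.shape[0]
    T = np.zeros((n, n_components))
    W = np.zeros((X.shape[1], n_components))
    for h in range(n_components):
        if np.linalg.norm(Y) < 1e-12:
            T = T[:, :h]
            W = W[:, :h]
            break
        col = int(np.argmax(np.linalg.norm(Y, axis=0)))
        u = Y[:, col] / np.linalg.norm(Y[:, col])
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = X.T @ u
            t = X @ w
            t /= np.linalg.norm(t)
            c = Y.T @ t
            u = Y @ c
            u /= np.linalg.norm(u)
            if np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
        c = Y.T @ t
        i_star = int(np.argmax(np.abs(c)))
        if c[i_star] < 0:
            t = -t
            u = -u
        T[:, h] = t
        W[:, h] = X.T @ u
        # deflate both matrices by the score projector
        X = X - np.outer(t, t @ X)
        Y = Y - np.outer(t, t @ Y)
    return T, W


def rd_oracle(t, Y) -> float:
    """Mean squared Pearson correlation, computed per column with numpy."""
    Y = np.asarray(Y, dtype=float)
    vals = []
    for m in range(Y.shape[1]):
        y = Y[:, m]
        if y.std() < 1e-15 or np.std(t) < 1e-15:
            vals.append(0.0)
        else:
            vals.append(float(np.corrcoef(t, y)[0, 1]) ** 2)
    return float(np.mean(vals))


def primal_importance(X, labels, n_components, max_components_cap=None):
    """Eq.-(1)-style gene importances from the primal oracle's scores.

    Loadings are X' t_h scaled to unit norm, weighted by the oracle's own
    Rd computation; mirrors the package's scoring arithmetic but runs it
    entirely on the primal route.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    Y0 = one_hot_centered(labels)
    T, _ = primal_nipals(Xc, Y0, n_components)
    raw = np.zeros(X.shape[1])
    for h in range(T.shape[1]):
        w = Xc.T @ T[:, h]
        nw = np.linalg.norm(w)
        if nw > 1e-15:
            w = w / nw
        raw += rd_oracle(T[:, h], Y0) * w**2
    return raw / raw.sum()
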