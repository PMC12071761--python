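"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (dense double loops, full p-by-p
eigendecompositions, exhaustive enumeration) and shares no code path with
the package implementation it checks.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def scatter_double_loop(X, y):
    """Sw, Sb, St by explicit outer-product summation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y.astype(str))
    p = X.shape[1]
    mu = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    St = np.zeros((p, p))
    for c in classes:
        Xc = X[y.astype(str) == c]
        mc = Xc.mean(axis=0)
        for x in Xc:
            Sw += np.outer(x - mc, x - mc)
        Sb += Xc.shape[0] * np.outer(mc - mu, mc - mu)
    for x in X:
        St += np.outer(x - mu, x - mu)
    return Sw, Sb, St


def _top_eigvecs(M, d):
    """Leading d eigenvectors of a symmetric matrix, descending."""
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    return V[:, np.argsort(w)[::-1][:d]]


def fisher_lda_dense(X, y, d):
    """Classical Fisher directions: generalized eigvecs of Sb w = l Sw w."""
    Sw, Sb, _ = scatter_double_loop(X, y)
    w, V = scipy.linalg.eigh(Sb, Sw)
    return V[:, np.argsort(w)[::-1][:d]]


def alda_dense(X, y, d, zero_tol=1e-10):
    """ALDA by the literal dense step list.

    Range space of St, reduced scatters, SVD of the reduced within-class
    scatter, replacement of near-zero singular-value roots by the largest
    one, and a dense (non-symmetric) eigensolve of S_alpha^-1 Sb_hat.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    _, _, St = scatter_double_loop(X, y)
    w_t, V_t = np.linalg.eigh(St)
    keep = w_t > zero_tol * w_t.max()
    Ut = V_t[:, keep]
    Y = (X - mu) @ Ut
    Sw_h, Sb_h, _ = scatter_double_loop(Y, y)
    w_w, U_w = np.linalg.eigh(Sw_h)
    w_w = np.clip(w_w, 0.0, None)
    Dw = np.sqrt(w_w)
    alpha = Dw.max()
    D_alpha = np.where(Dw < np.sqrt(zero_tol) * alpha, alpha, Dw)
    S_alpha_inv = U_w @ np.diag(D_alpha**-2.0) @ U_w.T
    evals, evecs = np.linalg.eig(S_alpha_inv @ Sb_h)
    order = np.argsort(evals.real)[::-1][:d]
    return Ut @ evecs[:, order].real


def mlda_dense(X, y, d, zero_tol=1e-12):
    """MLDA by dense eigenvalue clamping of the pooled covariance."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    K = np.unique(y.astype(str)).size
    Sw, Sb, _ = scatter_double_loop(X, y)
    Sp = Sw / (n - K)
    lam, V = np.linalg.eigh(Sp)
    lam_bar = lam.mean()
    lam_star = np.maximum(lam, lam_bar)
    Sw_star = V @ np.diag(lam_star) @ V.T * (n - K)
    w, W = scipy.linalg.eigh(Sb, Sw_star)
    return W[:, np.argsort(w)[::-1][:d]]


def nlda_dense(X, y, d, zero_tol=1e-10):
    """NLDA by a dense SVD of Sw and projection of Sb onto its null space."""
    X = np.asarray(X, dtype=float)
    Sw, Sb, _ = scatter_double_loop(X, y)
    U, s, Vt = np.linalg.svd(Sw)
    null = s <= zero_tol * max(s.max(), 1e-300)
    # svd of an exactly-zero Sw returns all-zero singular values
    if s.max() == 0:
        null = np.ones_like(s, dtype=bool)
    Q = Vt[null].T
    Sb_t = Q.T @ Sb @ Q
    return Q @ _top_eigvecs(Sb_t, d)


def best_split_exhaustive(X, y):
    """Every (feature, midpoint) pair scored by weighted child Gini."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y.astype(str))
    n = X.shape[0]

    def gini(labels):
        if labels.size == 0:
            return 0.0
        _, cnt = np.unique(labels.astype(str), return_counts=True)
        pk = cnt / cnt.sum()
        return 1.0 - np.sum(pk**2)

    best = None
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2.0
            left = y[X[:, j] <= thr]
            right = y[X[:, j] > thr]
            g = (left.size * gini(left) + right.size * gini(right)) / n
            if best is None or g < best[0] - 1e-15:
                best = (g, j, thr)
    if best is None:
        return None
    g, j, thr = best
    return j, thr, g


def subspace_angle(W1, W2):
    """Largest principal angle (radians) between two column spaces."""
    Q1, _ = np.linalg.qr(np.atleast_2d(W1))
    Q2, _ = np.linalg.qr(np.atleast_2d(W2))
    sv = np.linalg.svd(Q1.T @ Q2, compute_uv=False)
    return float(np.arccos(np.clip(sv.min(), -1.0, 1.0)))


def random_sss_instance(rng, p, n_per_class, K, spread=3.0):
    """Small labeled Gaussian instance with p >= total sample count."""
    centers = rng.normal(scale=spread, size=(K, p))
    X = np.vstack([
        centers[k] + rng.normal(size=(n_per_class, p)) for k in range(K)
    ])
    y = np.repeat([f"c{k}" for k in range(K)], n_per_class)
    return X, y
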