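"""Discriminant feature extraction when the within-class scatter is singular.

Classical Fisher LDA maximizes ``w' Sb w / w' Sw w`` and needs ``Sw`` to be
invertible.  In high-dimensional spectroscopy the feature dimension p far
exceeds the number of training spectra n (the small-sample-size regime), so
``Sw`` has rank at most ``n - K`` and is singular.  This module implements
four classical remedies, all sharing one scatter-matrix foundation:

* **ALDA** (approximate LDA): work in the range space of the total scatter
  ``St``; invert the reduced within-class scatter after replacing its
  (near-)zero singular values with the largest one, giving an invertible
  approximation of ``Sw^-1`` that keeps both range- and null-space
  directions.
* **CLDA** (common-vector LDA): project one sample of each class onto the
  null space of ``Sw`` — every sample of a class has the same image there
  (its *common vector*) — and discriminate with the scatter of these
  common vectors.
* **MLDA** (maximum-uncertainty LDA): eigendecompose the pooled covariance
  ``Sp = Sw / (n - K)`` and raise every eigenvalue below the average
  eigenvalue up to that average, producing a nonsingular ``Sw*`` for the
  Fisher criterion.
* **NLDA** (null-space LDA): restrict the between-class scatter to the
  null space of ``Sw`` — where within-class variation vanishes entirely —
  and take the leading eigenvectors there.  If ``Sw`` happens to be full
  rank, fall back to the eigenvectors of ``(Sb + Sw)^-1 Sb``.

All fitters accept the raw data matrix and labels; internally they exploit
the low rank of the scatter matrices (Gram-matrix / thin-SVD identities) so
that no p-by-p eigendecomposition is ever formed, which keeps a
1577-dimensional fit in the tens of milliseconds.  Dense small-p oracles in
the test suite confirm the equivalence.

Determinism: eigenvalues are sorted descending and each eigenvector's sign
is fixed by making its largest-magnitude entry positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

__all__ = [
    "ScatterSet",
    "ProjectionModel",
    "ExtractorNotApplicableError",
    "NoDiscriminantInformationError",
    "compute_scatter",
    "fit_alda",
    "fit_clda",
    "fit_mlda",
    "fit_nlda",
    "fit_extractor",
    "project",
    "principal_angles",
]

EXTRACTORS = ("ALDA", "CLDA", "MLDA", "NLDA")


class ExtractorNotApplicableError(ValueError):
    """The method's preconditions do not hold for this data (e.g. CLDA with
    a nonsingular within-class scatter); callers should use another method."""


class NoDiscriminantInformationError(ValueError):
    """All class means coincide in the considered subspace."""


@dataclass
class ScatterSet:
    """Within-, between- and total-class scatter with class statistics.

    Satisfies ``St = Sw + Sb`` and all three matrices are symmetric PSD.
    """

    Sw: np.ndarray
    Sb: np.ndarray
    St: np.ndarray
    class_means: np.ndarray  # (K, p)
    grand_mean: np.ndarray  # (p,)
    class_counts: np.ndarray  # (K,)
    classes: np.ndarray  # (K,) sorted labels


@dataclass
class ProjectionModel:
    """Fitted discriminant directions.

    ``W`` has shape (p, d) with unit-norm, full-column-rank columns;
    ``project`` maps a sample x to ``(x - grand_mean) @ W``.
    """

    method: str
    W: np.ndarray
    d: int
    eigenvalues: np.ndarray
    rank_tolerance: float
    grand_mean: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def _class_stats(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y.astype(str), return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx, minlength=classes.size).astype(float)
    means = np.stack([X[y_idx == k].mean(axis=0) for k in range(classes.size)])
    grand = X.mean(axis=0)
    return X, y_idx, classes, counts, means, grand


def compute_scatter(X: np.ndarray, y: np.ndarray) -> ScatterSet:
    """Dense scatter matrices Sw, Sb, St = Sw + Sb.

    Sw = sum_c sum_{i in c} (x_i - mu_c)(x_i - mu_c)';
    Sb = sum_c n_c (mu_c - mu)(mu_c - mu)';
    St = sum_i (x_i - mu)(x_i - mu)'.
    """
    X, y_idx, classes, counts, means, grand = _class_stats(X, y)
    A = X - means[y_idx]  # within-class centered
    Sw = A.T @ A
    Hb = (means - grand) * np.sqrt(counts)[:, None]
    Sb = Hb.T @ Hb
    Xc = X - grand
    St = Xc.T @ Xc
    return ScatterSet(
        Sw=Sw, Sb=Sb, St=St, class_means=means, grand_mean=grand,
        class_counts=counts.astype(int), classes=classes,
    )


def _default_tol(shape: tuple[int, int], sigma_max: float) -> float:
    """Numerical-rank cutoff: max(p, n) * eps * sigma_max."""
    return max(shape) * np.finfo(float).eps * sigma_max


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    if W.size == 0:
        return W
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def _normalize_columns(W: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    return W / norms


def _truncate_d(d_requested: int, d_avail: int, diagnostics: dict) -> int:
    if d_avail < d_requested:
        msg = (
            f"requested {d_requested} components but only {d_avail} usable "
            f"directions exist; returning {d_avail}"
        )
        diagnostics["truncation_warning"] = msg
        warnings.warn(msg, RuntimeWarning, stacklevel=3)
    return min(d_requested, d_avail)


def fit_alda(
    X: np.ndarray,
    y: np.ndarray,
    d: Optional[int] = None,
    rank_tolerance: Optional[float] = None,
) -> ProjectionModel:
    """Approximate LDA.

    1. Eigendecompose St (via thin SVD of the centered data) and keep the
       eigenvectors ``Ut`` of its range space; reduce: ``Y = (X - mu) Ut``.
    2. Form the reduced scatters ``Sw_hat``, ``Sb_hat`` and the SVD of
       ``Sw_hat`` with singular-value square roots ``D_W``.
    3. ``alpha = max(D_W)``; entries of ``D_W`` below
       ``rel_tol * alpha`` are replaced by ``alpha``, defining the
       invertible approximation ``S_alpha^-1 = U_W D_alpha^-2 U_W'``.
    4. Solve ``S_alpha^-1 Sb_hat w = lambda w``; map back ``W = Ut w`` and
       normalize columns.
    """
    X, y_idx, classes, counts, means, grand = _class_stats(X, y)
    n, p = X.shape
    K = classes.size
    if d is None:
        d = K - 1
    diagnostics: dict = {}

    # Step 1: range space of St from the thin SVD of the centered data.
    Xc = X - grand
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    st_eigs = s**2
    tol_st = rank_tolerance if rank_tolerance is not None else _default_tol(
        (n, p), st_eigs[0] if st_eigs.size else 0.0
    )
    keep = st_eigs > tol_st
    Ut = Vt[keep].T  # (p, t)
    t = Ut.shape[1]
    diagnostics["st_range_dim"] = t
    Y = Xc @ Ut  # (n, t)

    # Step 2: reduced within/between scatter.
    red = compute_scatter(Y, y)
    Sw_hat, Sb_hat = red.Sw, red.Sb
    eigw, Uw = np.linalg.eigh(Sw_hat)
    eigw = np.clip(eigw[::-1], 0.0, None)  # descending
    Uw = Uw[:, ::-1]
    Dw = np.sqrt(eigw)

    # Step 3: replace near-zero singular-value roots by alpha.  The rank
    # cutoff is a relative *eigenvalue* tolerance; on the square-root
    # scale of D_W it becomes sqrt(tol), so an eigenvalue at round-off
    # level (tol * alpha^2) is caught.
    alpha = Dw[0] if Dw.size else 0.0
    rel_tol = rank_tolerance if rank_tolerance is not None else _default_tol(
        (t, t), 1.0
    )
    replaced = Dw < np.sqrt(rel_tol) * alpha
    D_alpha = np.where(replaced, alpha, Dw)
    diagnostics["alpha"] = float(alpha)
    diagnostics["n_replaced"] = int(replaced.sum())

    # Step 4: S_alpha^-1 Sb_hat w = lambda w, solved through the symmetric
    # whitened form C = D_alpha^-1 Uw' Sb_hat Uw D_alpha^-1: eigenvectors
    # v of C give w = Uw D_alpha^-1 v with the same eigenvalues.
    M = (Uw / D_alpha).T @ Sb_hat @ (Uw / D_alpha)
    evals, V = np.linalg.eigh((M + M.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = (Uw / D_alpha) @ V[:, order]
    d_avail = int(np.sum(evals > max(evals[0], 0.0) * 1e-12)) if evals.size else 0
    d_use = _truncate_d(d, max(d_avail, 1), diagnostics)
    W = _normalize_columns(Ut @ evecs[:, :d_use])
    W = _fix_signs(W)
    return ProjectionModel(
        method="ALDA", W=W, d=d_use, eigenvalues=evals[:d_use],
        rank_tolerance=rel_tol, grand_mean=grand, diagnostics=diagnostics,
    )


def fit_clda(
    X: np.ndarray,
    y: np.ndarray,
    rank_tolerance: Optional[float] = None,
) -> ProjectionModel:
    """Common-vector LDA.

    1. ``Q`` = orthonormal basis of range(Sw), obtained from the nonzero
       eigenpairs of the small Gram matrix ``A A'`` of the within-class
       centered data A.
    2. For one sample per class (the first; by the common-vector theorem
       the choice is immaterial), remove the range-space component:
       ``x_com_c = x_c - Q Q' x_c``.
    3. ``W`` = nonzero-eigenvalue eigenvectors of the scatter of the common
       vectors about their mean (again via the Gram trick).

    Requires Sw to be singular (p > rank(Sw)); otherwise the null space is
    empty and an :class:`ExtractorNotApplicableError` is raised.
    """
    X, y_idx, classes, counts, means, grand = _class_stats(X, y)
    n, p = X.shape
    K = classes.size
    diagnostics: dict = {}

    A = X - means[y_idx]
    gram = A @ A.T
    eigv, eigvec = np.linalg.eigh(gram)
    eigv = np.clip(eigv[::-1], 0.0, None)
    eigvec = eigvec[:, ::-1]
    # Rank cutoff anchored to the total-scatter scale (Sw <= St in the PSD
    # order), so an Sw that is pure round-off relative to the data counts
    # as zero.
    st_scale = float(np.sum((X - grand) ** 2, axis=1).max()) * n
    tol = rank_tolerance if rank_tolerance is not None else _default_tol(
        (n, p), max(eigv[0] if eigv.size else 0.0, np.finfo(float).eps * st_scale)
    )
    nz = eigv > tol
    r = int(nz.sum())
    diagnostics["rank_Sw"] = r
    diagnostics["null_dim"] = p - r
    if r >= p:
        raise ExtractorNotApplicableError(
            "within-class scatter is nonsingular; CLDA needs a nonempty "
            "null space — use ALDA/MLDA/NLDA instead"
        )
    # Orthonormal range-space basis: Q = A' u / sqrt(lambda).
    Q = A.T @ (eigvec[:, nz] / np.sqrt(eigv[nz]))  # (p, r)

    first_idx = np.array([np.nonzero(y_idx == k)[0][0] for k in range(K)])
    Xrep = X[first_idx]
    Xcom = Xrep - (Xrep @ Q) @ Q.T if r else Xrep.copy()
    diagnostics["common_vectors"] = Xcom

    Acom = Xcom - Xcom.mean(axis=0)
    gram_com = Acom @ Acom.T
    ev2, evec2 = np.linalg.eigh(gram_com)
    ev2 = np.clip(ev2[::-1], 0.0, None)
    evec2 = evec2[:, ::-1]
    tol2 = rank_tolerance if rank_tolerance is not None else _default_tol(
        (K, p), ev2[0] if ev2.size else 0.0
    )
    nz2 = ev2 > tol2
    if not nz2.any():
        raise NoDiscriminantInformationError(
            "all class common vectors coincide; no discriminant directions"
        )
    W = Acom.T @ (evec2[:, nz2] / np.sqrt(ev2[nz2]))
    W = _fix_signs(_normalize_columns(W))
    d = W.shape[1]  # <= K - 1 by construction
    return ProjectionModel(
        method="CLDA", W=W, d=d, eigenvalues=ev2[nz2],
        rank_tolerance=tol, grand_mean=grand, diagnostics=diagnostics,
    )


def fit_mlda(
    X: np.ndarray,
    y: np.ndarray,
    d: Optional[int] = None,
    rank_tolerance: Optional[float] = None,
) -> ProjectionModel:
    """Maximum-uncertainty LDA.

    The pooled covariance ``Sp = Sw / (n - K)`` is eigendecomposed; every
    eigenvalue below the average eigenvalue ``lambda_bar`` (including the
    exact zeros of the singular case) is raised to ``lambda_bar``, giving
    ``Sw* = V Lambda* V' (n - K)``.  ``W`` solves the Fisher criterion with
    ``Sw*`` in place of ``Sw``.

    Implementation detail: the generalized eigenproblem
    ``Sb w = lambda Sw* w`` is solved in the (at most n + K dimensional)
    subspace spanned by range(Sw) and the class-mean deviations, which
    provably contains every eigenvector with a nonzero eigenvalue.
    """
    X, y_idx, classes, counts, means, grand = _class_stats(X, y)
    n, p = X.shape
    K = classes.size
    if n <= K:
        raise ValueError("MLDA needs n > n_classes (pooled covariance undefined)")
    if d is None:
        d = K - 1
    diagnostics: dict = {}

    A = X - means[y_idx]
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    lam = s**2 / (n - K)  # nonzero eigenvalues of Sp (descending)
    tol = rank_tolerance if rank_tolerance is not None else _default_tol(
        (n, p), lam[0] if lam.size else 0.0
    )
    nz = lam > tol
    r = int(nz.sum())
    if r == 0:
        raise ValueError("within-class scatter is exactly zero; MLDA undefined")
    Vr = Vt[:r].T  # (p, r) range-space eigenvectors of Sp
    lam_r = lam[:r]
    lam_bar = lam[:r].sum() / p  # average over ALL p eigenvalues (rest are 0)
    lam_star = np.maximum(lam_r, lam_bar)
    diagnostics["lambda_bar"] = float(lam_bar)
    diagnostics["rank_Sw"] = r
    diagnostics["n_clamped"] = int(np.sum(lam_r < lam_bar)) + (p - r)

    Hb = ((means - grand) * np.sqrt(counts)[:, None]).T  # (p, K)
    # Subspace containing all nonzero-eigenvalue solutions.
    B, _ = np.linalg.qr(np.hstack([Vr, Hb]))
    m = B.shape[1]
    BVr = B.T @ Vr  # (m, r)
    Sw_star_red = (n - K) * (
        (BVr * (lam_star - lam_bar)) @ BVr.T + lam_bar * np.eye(m)
    )
    G = B.T @ Hb
    Sb_red = G @ G.T
    evals, evecs = scipy.linalg.eigh(Sb_red, Sw_star_red)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    d_avail = int(np.sum(evals > max(evals[0], 0.0) * 1e-12)) if evals.size else 0
    d_use = _truncate_d(d, max(d_avail, 1), diagnostics)
    W = _fix_signs(_normalize_columns(B @ evecs[:, :d_use]))
    return ProjectionModel(
        method="MLDA", W=W, d=d_use, eigenvalues=evals[:d_use],
        rank_tolerance=tol, grand_mean=grand, diagnostics=diagnostics,
    )


def fit_nlda(
    X: np.ndarray,
    y: np.ndarray,
    d: Optional[int] = None,
    rank_tolerance: Optional[float] = None,
) -> ProjectionModel:
    """Null-space LDA.

    If Sw has full rank p the classical criterion applies directly:
    ``W`` = leading eigenvectors of ``(Sb + Sw)^-1 Sb``.  Otherwise ``Sb``
    is projected onto null(Sw) and the leading eigenvectors of the
    projected matrix — directions with zero within-class variance and
    maximal between-class spread — form ``W`` (orthonormal columns).

    The computation runs inside range(St): the part of null(Sw) orthogonal
    to the data carries no between-class scatter, so discarding it changes
    nothing (dense oracle-checked in the tests).
    """
    X, y_idx, classes, counts, means, grand = _class_stats(X, y)
    n, p = X.shape
    K = classes.size
    if d is None:
        d = K - 1
    diagnostics: dict = {}

    A = X - means[y_idx]
    sv_w = np.linalg.svd(A, compute_uv=False)
    sw_eigs = sv_w**2  # singular values of Sw
    # Anchored to the total-scatter scale as in fit_clda: an Sw at pure
    # round-off level has an empty range, not a full one.
    st_scale = float(np.sum((X - grand) ** 2, axis=1).max()) * n
    tol = rank_tolerance if rank_tolerance is not None else _default_tol(
        (p, p),
        max(sw_eigs[0] if sw_eigs.size else 0.0, np.finfo(float).eps * st_scale),
    )
    r = int(np.sum(sw_eigs > tol))
    diagnostics["rank_Sw"] = r
    diagnostics["null_dim"] = p - r

    Hb = ((means - grand) * np.sqrt(counts)[:, None]).T  # (p, K)

    if r == p:
        # Full-rank fallback: eigenvectors of (Sb + Sw)^-1 Sb.
        diagnostics["full_rank_fallback"] = True
        Sw = A.T @ A
        Sb = Hb @ Hb.T
        evals, evecs = scipy.linalg.eigh(Sb, Sb + Sw)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        d_avail = int(np.sum(evals > max(evals[0], 0.0) * 1e-12)) if evals.size else 0
        d_use = _truncate_d(d, max(d_avail, 1), diagnostics)
        W = _fix_signs(_normalize_columns(evecs[:, :d_use]))
        return ProjectionModel(
            method="NLDA", W=W, d=d_use, eigenvalues=evals[:d_use],
            rank_tolerance=tol, grand_mean=grand, diagnostics=diagnostics,
        )

    # Reduce to range(St): T spans the data (within + between deviations).
    Xc = X - grand
    _, st_s, Vt_t = np.linalg.svd(Xc, full_matrices=False)
    st_eigs = st_s**2
    tol_t = _default_tol((n, p), st_eigs[0] if st_eigs.size else 0.0)
    T = Vt_t[st_eigs > tol_t].T  # (p, t)
    t = T.shape[1]

    Ar = A @ T  # (n, t)
    Sw_r = Ar.T @ Ar
    eigw, V = np.linalg.eigh(Sw_r)  # ascending
    null_mask = eigw <= tol
    q = int(null_mask.sum())
    diagnostics["effective_null_dim"] = q
    if q == 0:
        raise NoDiscriminantInformationError(
            "null(Sw) carries no between-class scatter for this data"
        )
    Qr = V[:, null_mask]  # (t, q)
    Gb = (Hb.T @ T) @ Qr  # (K, q): Sb projected factor
    Sb_null = Gb.T @ Gb
    evals, evecs = np.linalg.eigh(Sb_null)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    tol_b = _default_tol((q, q), evals[0] if evals.size else 0.0)
    d_avail = int(np.sum(evals > tol_b))
    if d_avail == 0:
        raise NoDiscriminantInformationError(
            "all class means coincide in the null space of Sw"
        )
    d_use = _truncate_d(d, d_avail, diagnostics)
    W = T @ (Qr @ evecs[:, :d_use])  # orthonormal columns by construction
    W = _fix_signs(W)
    return ProjectionModel(
        method="NLDA", W=W, d=d_use, eigenvalues=evals[:d_use],
        rank_tolerance=tol, grand_mean=grand, diagnostics=diagnostics,
    )


def fit_extractor(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    d: Optional[int] = None,
    rank_tolerance: Optional[float] = None,
) -> ProjectionModel:
    """Dispatch to one of the four extractors by name."""
    method = method.upper()
    if method == "ALDA":
        return fit_alda(X, y, d=d, rank_tolerance=rank_tolerance)
    if method == "CLDA":
        return fit_clda(X, y, rank_tolerance=rank_tolerance)
    if method == "MLDA":
        return fit_mlda(X, y, d=d, rank_tolerance=rank_tolerance)
    if method == "NLDA":
        return fit_nlda(X, y, d=d, rank_tolerance=rank_tolerance)
    raise ValueError(f"unknown extractor {method!r}; valid: {EXTRACTORS}")


def project(model: ProjectionModel, X: np.ndarray) -> np.ndarray:
    """Discriminant scores ``(X - grand_mean_train) @ W``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} features but the model expects {model.W.shape[0]}"
        )
    return (X - model.grand_mean) @ model.W


def principal_angles(W1: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """Principal angles (radians) between the column spaces of W1 and W2."""
    Q1, _ = np.linalg.qr(W1)
    Q2, _ = np.linalg.qr(W2)
    sv = np.linalg.svd(Q1.T @ Q2, compute_uv=False)
    return np.arccos(np.clip(sv, -1.0, 1.0))
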