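"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a route different from the package
implementation: direct formulas, exhaustive search, or enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def svd_pls_predict(X: np.ndarray, Y: np.ndarray, n_components: int) -> np.ndarray:
    """Reference PLS2 training predictions via exact per-component SVD.

    Each component's X-weight vector is the leading left singular
    vector of the cross-covariance X_k' Y_k (computed directly by SVD
    rather than by power iteration), followed by the standard score /
    loading / deflation steps. Predictions are gauge-invariant, so this
    is directly comparable with any correct PLS regression.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xk, Yk = X - xm, Y - ym
    m, p = X.shape[1], Y.shape[1]
    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    Q = np.zeros((p, n_components))
    for k in range(n_components):
        U, _, _ = np.linalg.svd(Xk.T @ Yk, full_matrices=False)
        w = U[:, 0]
        t = Xk @ w
        tt = t @ t
        q = Yk.T @ t / tt
        pk = Xk.T @ t / tt
        Xk = Xk - np.outer(t, pk)
        Yk = Yk - np.outer(t, q)
        W[:, k], P[:, k], Q[:, k] = w, pk, q
    R = W @ np.linalg.inv(P.T @ W)
    return (X - xm) @ (R @ Q.T) + ym


def welch_closed_form(a, b):
    """Welch statistic, df and two-sided p from the textbook formulas."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def bh_step_up(pvals):
    """Literal step-up definition: q_(i) = min_{k >= i} p_(k) m / k."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def ols_beta_t(y, X):
    """Closed-form least squares: beta = (X'X)^-1 X'y and the t of each
    coefficient from the classical covariance estimate."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    return beta, beta / se


def brute_force_assign(coords_mm, parcellation, tolerance_mm=2.0):
    """Containment-then-nearest assignment by exhaustive scan over every
    labeled voxel (no spatial index); ties at equal distance resolve to
    the lower region id."""
    labels = parcellation.labels
    vox_idx, vox_labels = parcellation.labeled_voxels()
    centers = parcellation.voxel_to_mm(vox_idx)
    out_region, out_dist = [], []
    for pt in np.atleast_2d(coords_mm):
        d = np.linalg.norm(centers - pt, axis=1)
        dmin = d.min()
        vi = np.rint(parcellation.mm_to_voxel(pt)[0]).astype(int)
        region = 0
        if np.all(vi >= 0) and np.all(vi < np.asarray(labels.shape)):
            lab = int(labels[tuple(vi)])
            if lab > 0:
                region = lab
        if region == 0 and dmin <= tolerance_mm:
            cand = vox_labels[d <= dmin + 1e-9]
            region = int(cand.min())
        out_region.append(region)
        out_dist.append(dmin)
    return np.asarray(out_region), np.asarray(out_dist)


def running_sum_es(ordered_weights, is_hit, exponent=1.0):
    """Hand-loop weighted KS enrichment score on an explicit ranking."""
    w = np.abs(np.asarray(ordered_weights, float)) ** exponent
    is_hit = np.asarray(is_hit, bool)
    nh = int(is_hit.sum())
    n = len(w)
    hit_total = w[is_hit].sum()
    run = 0.0
    best = 0.0
    for i in range(n):
        if is_hit[i]:
            run += (w[i] / hit_total) if hit_total > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


def enumerate_null_es(ranked, set_size, exponent=1.0):
    """All C(N, s) same-size subset enrichment scores of a ranking,
    each computed with the hand-loop running sum."""
    genes = list(ranked.index)
    w = ranked.to_numpy(dtype=float)
    n = len(genes)
    out = []
    for c in combinations(range(n), set_size):
        is_hit = np.zeros(n, dtype=bool)
        is_hit[list(c)] = True
        out.append(running_sum_es(w, is_hit, exponent=exponent))
    return np.asarray(out)
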