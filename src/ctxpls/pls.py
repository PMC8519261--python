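"""NIPALS partial least squares regression.

Implements PLS regression (PLS2) by the classical NIPALS iteration with
per-component deflation of both blocks. For a predictor matrix ``X``
(n samples x m variables, here regions x genes) and response ``Y``
(n x p), each component k extracts

* a unit-norm X-weight vector ``w_k`` maximizing covariance between the
  X-score ``t_k = X_k w_k`` and the Y-score ``u_k``,
* X-loadings ``p_k = X_k' t_k / t_k' t_k`` used to deflate ``X``,
* Y-loadings ``q_k = Y_k' t_k / t_k' t_k`` used to deflate ``Y``,
* the inner-relation coefficient ``beta_k = u_k' t_k / t_k' t_k``.

Because deflation changes the basis of ``X`` from component to
component, the weights ``W`` do not map the original (centered)
predictors to scores; the rotated weights ``R = W (P'W)^{-1}`` do
(``T = X_c R``) and are the per-gene weights handed to the enrichment
stage. With a single response the inner loop converges in one pass and
``w_1`` is simply the normalized cross-covariance ``X_c' y_c``.

Preprocessing is column centering by default; unit-variance scaling is
optional and recorded on the fit. At ``K = rank(X_c)`` the training
predictions coincide with the ordinary least-squares fit of ``Y`` on
``X`` — a useful exactness limit for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class ConvergenceError(RuntimeError):
    """NIPALS inner loop failed to converge for some component."""


@dataclass
class PLSFit:
    """Fitted PLS model.

    Attributes follow the standard two-block notation: X-weights ``W``
    (m x K), X-scores ``T`` (n x K), X-loadings ``P`` (m x K), Y-scores
    ``U`` (n x K), Y-loadings ``Q`` (p x K), rotated weights ``R``
    (m x K), regression coefficients ``coef`` (m x p), and per-component
    inner coefficients and explained-variance fractions.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    x_scale: np.ndarray
    y_scale: np.ndarray
    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    U: np.ndarray
    Q: np.ndarray
    inner_coefs: np.ndarray
    R: np.ndarray
    coef: np.ndarray
    x_explained: np.ndarray  # fractions in [0, 1]
    y_explained: np.ndarray
    scaled: bool
    x_names: list | None = None
    y_names: list | None = None
    _ssx: float = field(default=0.0, repr=False)
    _ssy: float = field(default=0.0, repr=False)

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new predictor rows onto the component scores."""
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return Xc @ self.R

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict responses for new predictor rows."""
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return Xc @ self.coef * self.y_scale + self.y_mean


def _as_2d(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    scale: bool = False,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    x_names: list | None = None,
    y_names: list | None = None,
) -> PLSFit:
    """Fit a PLS regression with ``n_components`` NIPALS components.

    Parameters
    ----------
    X, Y:
        Predictor (n x m) and response (n x p, or length-n vector)
        arrays; no non-finite entries. Zero-variance predictor columns
        are legal and receive exactly zero weight.
    n_components:
        Number of latent components K, ``1 <= K <= min(n - 1, m)``.
    scale:
        If true, scale columns of both blocks to unit variance after
        centering (zero-variance columns keep scale 1).
    tol, max_iter:
        Convergence tolerance on the change of the weight vector and the
        iteration cap of the inner loop.

    Raises
    ------
    ValueError
        On shape/validity violations or when K exceeds the rank of the
        centered predictor block.
    ConvergenceError
        If the inner loop does not converge within ``max_iter``.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, m = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    p = Y.shape[1]
    if n < 3:
        raise ValueError("need at least 3 rows")
    K = int(n_components)
    if not 1 <= K <= min(n - 1, m):
        raise ValueError(f"n_components must be in [1, {min(n - 1, m)}], got {K}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite entries in X or Y")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        y_scale = Y.std(axis=0, ddof=1)
        x_scale[x_scale == 0.0] = 1.0
        y_scale[y_scale == 0.0] = 1.0
    else:
        x_scale = np.ones(m)
        y_scale = np.ones(p)
    X0 = (X - x_mean) / x_scale
    Y0 = (Y - y_mean) / y_scale
    ssx = float(np.sum(X0**2))
    ssy = float(np.sum(Y0**2))

    Xk, Yk = X0.copy(), Y0.copy()
    W = np.zeros((m, K))
    T = np.zeros((n, K))
    P = np.zeros((m, K))
    U = np.zeros((n, K))
    Q = np.zeros((p, K))
    beta = np.zeros(K)
    x_explained = np.zeros(K)
    y_explained = np.zeros(K)
    eps = np.finfo(float).eps

    for k in range(K):
        # start from the Y column with the largest remaining variance
        u = Yk[:, np.argmax(Yk.var(axis=0))].copy()
        if np.linalg.norm(u) < eps * max(1.0, np.sqrt(ssy)):
            u = np.ones(n)  # Y exhausted; extract a pure-X component
        w_old = np.zeros(m)
        for _ in range(max_iter):
            w = Xk.T @ u
            nw = np.linalg.norm(w)
            if nw <= 1e3 * eps * max(np.sqrt(ssx), 1.0) * max(np.linalg.norm(u), 1.0):
                raise ValueError(
                    f"X exhausted at component {k + 1}: rank(X) < n_components"
                )
            w /= nw
            t = Xk @ w
            tt = float(t @ t)
            if tt <= eps * max(ssx, 1.0):
                raise ValueError(
                    f"X exhausted at component {k + 1}: rank(X) < n_components"
                )
            q = Yk.T @ t / tt
            qq = float(q @ q)
            if qq > 0.0:
                u = Yk @ q / qq
            if np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        else:
            raise ConvergenceError(
                f"NIPALS did not converge for component {k + 1} in {max_iter} iterations"
            )
        # corr(t, u) >= 0 holds by construction (t'u is a quadratic form);
        # when it is numerically zero, fix the gauge by making the
        # largest-|weight| entry positive.
        tu = float(t @ u)
        if abs(tu) < eps * max(1.0, np.linalg.norm(t) * np.linalg.norm(u)):
            if w[np.argmax(np.abs(w))] < 0:
                w, t, u, q = -w, -t, -u, -q
        p_k = Xk.T @ t / tt
        # classical gauge for the inner relation: unit-norm Y-weight
        # c = q/|q|, Y-score u = Y_k c, beta_k regresses u on t. The
        # deflation below is gauge-invariant.
        qn = np.linalg.norm(q)
        if qn > 0:
            u = Yk @ (q / qn)
            beta[k] = float(u @ t) / tt
        else:
            u = np.zeros(n)
            beta[k] = 0.0
        Xk = Xk - np.outer(t, p_k)
        Yk = Yk - np.outer(t, q)
        W[:, k], T[:, k], P[:, k], U[:, k], Q[:, k] = w, t, p_k, u, q
        x_explained[k] = tt * float(p_k @ p_k) / ssx if ssx > 0 else 0.0
        y_explained[k] = tt * float(q @ q) / ssy if ssy > 0 else 0.0

    R = W @ np.linalg.inv(P.T @ W)
    coef = R @ Q.T
    return PLSFit(
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=x_scale,
        y_scale=y_scale,
        W=W,
        T=T,
        P=P,
        U=U,
        Q=Q,
        inner_coefs=beta,
        R=R,
        coef=coef,
        x_explained=x_explained,
        y_explained=y_explained,
        scaled=scale,
        x_names=list(x_names) if x_names is not None else None,
        y_names=list(y_names) if y_names is not None else None,
        _ssx=ssx,
        _ssy=ssy,
    )


def gene_weights(fit: PLSFit, component: int) -> np.ndarray:
    """Column ``component`` (1-based) of the rotated weight matrix R.

    These are the per-predictor weights that map centered predictors to
    the component score, and the ranking statistic for enrichment.
    """
    if not 1 <= component <= fit.n_components:
        raise ValueError(f"component must be in [1, {fit.n_components}]")
    return fit.R[:, component - 1].copy()


def explained_variance(fit: PLSFit) -> dict[str, np.ndarray]:
    """Per-component explained-variance percentages for X and Y."""
    return {
        "x_pct": 100.0 * fit.x_explained,
        "y_pct": 100.0 * fit.y_explained,
    }


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary.

    ``press[k]`` and ``rmsep[k]`` are indexed by component count
    k = 0..K_max (k = 0 is the fold-mean predictor);
    ``rmsep = sqrt(press / (n_folds_used * p))``.

    ``argmin_components`` is the plain RMSEP argmin over k >= 1 (ties
    to the smaller k). Because the CV curve is typically flat past the
    true dimensionality, the argmin flips to larger k on noise alone;
    ``optimal_components`` therefore applies the one-standard-error
    rule: the smallest k whose mean squared prediction error is within
    one standard error (over folds) of the argmin's. This is the same
    conservative selection the R ``pls`` toolchain offers.
    """

    press: np.ndarray
    rmsep: np.ndarray
    optimal_components: int
    argmin_components: int
    n_folds_used: int
    n_folds_skipped: int
    max_components: int


def loo_cv(
    X: np.ndarray,
    Y: np.ndarray,
    max_components: int,
    scale: bool = False,
) -> CVResult:
    """Leave-one-out component selection by predictive residual error.

    Each fold refits (including re-centering, so no information leaks
    from the held-out row) and predicts the held-out responses with
    every component count up to ``max_components``. Folds whose reduced
    predictor block cannot support the requested components are skipped
    and counted.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, m = X.shape
    p = Y.shape[1]
    if n < 4:
        raise ValueError("need at least 4 rows for leave-one-out")
    Kmax = int(max_components)
    if not 1 <= Kmax <= min(n - 2, m):
        raise ValueError(f"max_components must be in [1, {min(n - 2, m)}]")
    fold_err = np.full((n, Kmax + 1), np.nan)  # per-fold squared error
    skipped = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[:] = True
        mask[i] = False
        try:
            fit = fit_pls(X[mask], Y[mask], Kmax, scale=scale)
        except (ValueError, ConvergenceError):
            skipped += 1
            continue
        fold_err[i, 0] = float(np.sum((Y[i] - fit.y_mean) ** 2))
        xc = (X[i] - fit.x_mean) / fit.x_scale
        t_row = xc @ fit.R  # scores of the held-out row, all components
        for k in range(1, Kmax + 1):
            pred = t_row[:k] @ fit.Q[:, :k].T * fit.y_scale + fit.y_mean
            fold_err[i, k] = float(np.sum((Y[i] - pred) ** 2))
    ok = ~np.isnan(fold_err[:, 0])
    used = int(ok.sum())
    if used == 0:
        raise ValueError("every leave-one-out fold was degenerate")
    errs = fold_err[ok]
    press = errs.sum(axis=0)
    rmsep = np.sqrt(press / (used * p))
    argmin = 1 + int(np.argmin(rmsep[1:]))
    # one-standard-error rule over the per-fold errors at the argmin
    se = errs[:, argmin].std(ddof=1) / np.sqrt(used) if used > 1 else 0.0
    msep = press / used
    optimal = argmin
    for k in range(1, Kmax + 1):
        if msep[k] <= msep[argmin] + se:
            optimal = k
            break
    return CVResult(
        press=press,
        rmsep=rmsep,
        optimal_components=optimal,
        argmin_components=argmin,
        n_folds_used=used,
        n_folds_skipped=skipped,
        max_components=Kmax,
    )


def score_response_report(fit: PLSFit, Y: np.ndarray):
    """Correlations between component scores and responses.

    Returns ``(components, responses)`` as two pandas DataFrames: per
    component the Pearson r between the X-score ``t_k`` and Y-score
    ``u_k`` plus the inner coefficient, and per (component, response
    column) the Pearson r between ``t_k`` and the raw column together
    with the Y-loading ``Q[j, k]``. Zero-variance responses are flagged
    instead of given an r.
    """
    import pandas as pd

    Y = _as_2d(Y)
    if Y.shape[0] != fit.T.shape[0]:
        raise ValueError("Y row count does not match the fit")
    y_names = fit.y_names if fit.y_names is not None else list(range(Y.shape[1]))
    comp_rows = []
    resp_rows = []
    for k in range(fit.n_components):
        t = fit.T[:, k]
        u = fit.U[:, k]
        r_tu = (
            float(stats.pearsonr(t, u)[0])
            if t.std() > 0 and u.std() > 0
            else np.nan
        )
        comp_rows.append(
            {"component": k + 1, "r_t_u": r_tu, "inner_coef": fit.inner_coefs[k]}
        )
        for j in range(Y.shape[1]):
            y = Y[:, j].astype(float)
            flag = None
            if y.std() == 0 or t.std() == 0:
                r = np.nan
                flag = "zero-variance"
            else:
                r = float(stats.pearsonr(t, y)[0])
            resp_rows.append(
                {
                    "component": k + 1,
                    "response": y_names[j],
                    "r": r,
                    "q_loading": fit.Q[j, k],
                    "flag": flag,
                }
            )
    return pd.DataFrame(comp_rows), pd.DataFrame(resp_rows)
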