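"""Batched L1-penalized logistic path solver.

Solves, for a batch of P weighted problems sharing the sample dimension,

    min_{beta, b}  (1/W) sum_i w_i * logloss(y_i, x_i beta + b)  +  lambda ||beta||_1

over a decreasing per-problem penalty grid with warm starts, by accelerated
proximal gradient (FISTA) with an unpenalized intercept.  Batching is the
point: cross-validation folds and bootstrap resamples are stacked into one
tensor so the whole resampling layer runs as a handful of vectorized numpy
operations instead of thousands of independent small fits.

Inputs are standardized per problem (weighted mean/SD); zero-weight rows are
carried along so that held-out samples can be scored with the training
fold's standardization.
"""

from __future__ import annotations

import numpy as np

_ETA_CLIP = 30.0
_PROB_EPS = 1e-7


def soft_threshold(u: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(u) * np.maximum(np.abs(u) - t, 0.0)


def weighted_standardize(X: np.ndarray, w: np.ndarray):
    """Per-problem weighted standardization.

    X: (P, n, p); w: (P, n) nonnegative.  Returns (X_std, mu, sd); constant
    columns get sd = 1 (their coefficients stay exactly zero).
    """
    W = w.sum(axis=1, keepdims=True)
    mu = np.einsum("pn,pnj->pj", w, X) / W
    xc = X - mu[:, None, :]
    var = np.einsum("pn,pnj->pj", w, xc**2) / W
    sd = np.sqrt(var)
    sd[sd == 0] = 1.0
    return xc / sd[:, None, :], mu, sd


def lambda_max(X_std: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Smallest penalty at which every coefficient is zero, per problem."""
    W = w.sum(axis=1)
    ybar = (w * y).sum(axis=1) / W
    g = np.einsum("pnj,pn->pj", X_std, w * (y - ybar[:, None])) / W[:, None]
    return np.abs(g).max(axis=1)


def lambda_grid(lam_max: np.ndarray, n_lambda: int, ratio: float) -> np.ndarray:
    """Per-problem log-spaced decreasing grid from lambda_max down."""
    lam_max = np.atleast_1d(np.asarray(lam_max, dtype=float))
    t = np.linspace(0.0, 1.0, n_lambda)
    return lam_max[:, None] * np.power(ratio, t)[None, :]


def _lipschitz(A: np.ndarray, w: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Upper bound on the logistic-loss gradient Lipschitz constant.

    sigma_max^2(sqrt(w) A) / (4 W) per problem, via power iteration (the
    iteration count is fixed, so results are deterministic).
    """
    P, _, q = A.shape
    rng = np.random.default_rng(12345)
    v = rng.normal(size=(P, q))
    for _ in range(40):
        u = np.einsum("pnj,pj->pn", A, v)
        v = np.einsum("pnj,pn->pj", A, w * u)
        nv = np.linalg.norm(v, axis=1, keepdims=True)
        nv[nv == 0] = 1.0
        v = v / nv
    u = np.einsum("pnj,pj->pn", A, v)
    sigma2 = np.einsum("pn,pn->p", w * u, u)
    return 1.05 * sigma2 / (4.0 * W) + 1e-12


def fista_l1_logistic_path(
    X_std: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 1000,
    check_every: int = 10,
    dev_ratio_stop: float = 0.999,
):
    """Fit the penalty path for a batch of weighted problems.

    X_std: (P, n, p) standardized per problem; y, w: (P, n);
    lambdas: (P, L) decreasing.  Returns (coefs (P, L, p), intercepts (P, L)).

    Once a problem explains ``dev_ratio_stop`` of its null deviance, its
    solution is frozen for the remaining (smaller) penalties — the usual
    path-termination rule for saturated fits, where coefficients would
    otherwise grow without bound on separable data.
    """
    P, n, p = X_std.shape
    A = np.concatenate([X_std, np.ones((P, n, 1))], axis=2)
    W = w.sum(axis=1)
    Winv = (1.0 / W)[:, None]
    Lip = _lipschitz(A, w, W)[:, None]
    penmask = np.ones(p + 1)
    penmask[-1] = 0.0  # intercept unpenalized

    ybar = np.clip((w * y).sum(axis=1) / W, _PROB_EPS, 1 - _PROB_EPS)
    dev_null = -2.0 * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    dev_stop = (1.0 - dev_ratio_stop) * dev_null

    L_grid = lambdas.shape[1]
    out = np.empty((P, L_grid, p + 1))
    x_cur = np.zeros((P, p + 1))
    wy = w * y
    frozen = np.zeros(P, dtype=bool)
    for l_idx in range(L_grid):
        if frozen.all():
            out[:, l_idx:, :] = x_cur[:, None, :]
            break
        thresh = (lambdas[:, l_idx : l_idx + 1] / Lip) * penmask[None, :]
        x_prev = x_cur.copy()
        z = x_cur.copy()
        t_mom = np.ones((P, 1))
        for it in range(1, max_iter + 1):
            eta = np.einsum("pnj,pj->pn", A, z)
            np.clip(eta, -_ETA_CLIP, _ETA_CLIP, out=eta)
            mu = 1.0 / (1.0 + np.exp(-eta))
            grad = np.einsum("pnj,pn->pj", A, w * mu - wy) * Winv
            x_new = soft_threshold(z - grad / Lip, thresh)
            if frozen.any():
                x_new[frozen] = x_cur[frozen]
            # per-problem adaptive restart (gradient scheme): drop momentum
            # when the update opposes the previous step
            restart = np.einsum("pj,pj->p", z - x_new, x_new - x_prev) > 0
            t_mom[restart] = 1.0
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
            z = x_new + ((t_mom - 1.0) / t_new) * (x_new - x_prev)
            if frozen.any():
                z[frozen] = x_cur[frozen]
            done = it % check_every == 0 and float(
                np.max(np.abs(x_new - x_prev))
            ) < tol
            x_prev = x_new
            t_mom = t_new
            if done:
                break
        x_cur = x_prev
        out[:, l_idx, :] = x_cur
        # freeze saturated problems before moving to smaller penalties
        eta = np.einsum("pnj,pj->pn", A, x_cur)
        np.clip(eta, -_ETA_CLIP, _ETA_CLIP, out=eta)
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _PROB_EPS, 1 - _PROB_EPS)
        dev = -2.0 * (w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))).sum(
            axis=1
        ) / W
        frozen |= dev <= dev_stop
    return out[:, :, :p], out[:, :, p]


def batch_newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    ridge: float | np.ndarray = 0.0,
    tol: float = 1e-10,
    max_iter: int = 60,
):
    """Batched (optionally weighted) logistic regression via Newton-IRLS.

    X: (P, n, p); y: (P, n); w: (P, n) sample weights.  ``ridge`` is an L2
    penalty on the coefficients (never the intercept), scalar or per-problem.
    Returns (coefs (P, p), intercepts (P,), converged (P,)).
    """
    P, n, p = X.shape
    A = np.concatenate([X, np.ones((P, n, 1))], axis=2)
    if w is None:
        w = np.ones((P, n))
    W = w.sum(axis=1)
    ridge_vec = np.broadcast_to(np.asarray(ridge, dtype=float), (P,)).copy()
    ridge_vec = ridge_vec + 1e-12  # numerical floor keeps the Hessian SPD
    eye = np.eye(p + 1)
    eye[-1, -1] = 0.0
    theta = np.zeros((P, p + 1))
    converged = np.zeros(P, dtype=bool)
    for _ in range(max_iter):
        eta = np.einsum("pnj,pj->pn", A, theta)
        np.clip(eta, -_ETA_CLIP, _ETA_CLIP, out=eta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        s = w * mu * (1.0 - mu)
        g = (
            np.einsum("pnj,pn->pj", A, w * (mu - y)) / W[:, None]
            + ridge_vec[:, None] * (theta @ eye)
        )
        H = (
            np.einsum("pnj,pn,pnk->pjk", A, s, A) / W[:, None, None]
            + ridge_vec[:, None, None] * eye[None]
        )
        delta = np.linalg.solve(H, g[..., None])[..., 0]
        theta -= delta
        converged = np.max(np.abs(delta), axis=1) < tol
        if bool(converged.all()):
            break
    bad = ~np.isfinite(theta).all(axis=1)
    if bad.any():
        theta[bad] = 0.0
        converged[bad] = False
    return theta[:, :p], theta[:, p], converged


def batch_logistic_with_fallback(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    ridge_c: float = 1000.0,
    coef_blowup: float = 1e4,
):
    """Unpenalized batched logistic with a ridge-stabilized fallback.

    Problems whose maximum-likelihood fit fails to converge or blows up
    (separation) are refit with a small L2 penalty (1 / (ridge_c * n) per
    the usual C parameterization).  Returns (coefs, intercepts, flagged).
    """
    P, n, _ = X.shape
    coefs, intercepts, converged = batch_newton_logistic(X, y, w)
    flagged = (~converged) | (np.abs(coefs).max(axis=1) > coef_blowup)
    if flagged.any():
        idx = np.flatnonzero(flagged)
        c2, i2, _ = batch_newton_logistic(
            X[idx],
            y[idx],
            None if w is None else w[idx],
            ridge=1.0 / (ridge_c * n),
        )
        coefs[idx] = c2
        intercepts[idx] = i2
    return coefs, intercepts, flagged


def path_deviance(
    X_std: np.ndarray,
    y: np.ndarray,
    eval_w: np.ndarray,
    coefs: np.ndarray,
    intercepts: np.ndarray,
) -> np.ndarray:
    """Per-problem, per-lambda mean binomial deviance over ``eval_w`` rows.

    ``X_std`` must be standardized with the fitting problem's statistics.
    Returns (P, L).
    """
    eta = np.einsum("pnj,plj->pnl", X_std, coefs) + intercepts[:, None, :]
    np.clip(eta, -_ETA_CLIP, _ETA_CLIP, out=eta)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _PROB_EPS, 1.0 - _PROB_EPS)
    ll = y[:, :, None] * np.log(mu) + (1.0 - y[:, :, None]) * np.log(1.0 - mu)
    Wev = eval_w.sum(axis=1)[:, None]
    return -2.0 * np.einsum("pn,pnl->pl", eval_w, ll) / Wev
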