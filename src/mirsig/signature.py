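"""L1-penalized logistic signature discovery and its uncertainty checks.

The signature is the set of assays with nonzero coefficients of an
L1-penalized (LASSO) binomial model fitted on normalized Ct values of the
differentially expressed assays, at the one-standard-error penalty
``lambda_1se``: the largest lambda whose 10-fold cross-validated binomial
deviance is within one standard error of the minimum.  Features are
standardized internally; coefficients are reported on both scales.

Two resampling checks accompany the point estimate:

* a bootstrap stability test -- the selection is rerun on B resamples of the
  cohort and the frequency with which at least half of the original
  signature reappears is recorded; the stability p-value is one minus that
  frequency, so small p means a stable signature;
* a random-signature null -- M random assay subsets of the same size are
  fitted and evaluated under the identical protocol, and the observed
  accuracy is ranked within the resulting null distribution with the
  add-one rule p = (1 + #{acc_random >= acc_observed}) / (M + 1).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import _solver
from ._logistic import fit_logistic
from .data import MirsigError
from .evaluate import confusion_metrics, select_threshold_min_fpr

_NONZERO_TOL = 1e-8
_SOLVER_TOL = 1e-7
_SOLVER_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# Path fitting

@dataclass
class LassoPath:
    feature_names: list
    lambdas: np.ndarray            # decreasing
    coefs_std: np.ndarray          # n_lambda x p, standardized scale
    intercepts_std: np.ndarray
    x_mean: pd.Series
    x_sd: pd.Series
    X: pd.DataFrame                # samples x retained features (original scale)
    y: np.ndarray
    dropped_features: list = field(default_factory=list)

    @property
    def n_nonzero(self) -> np.ndarray:
        return (np.abs(self.coefs_std) > _NONZERO_TOL).sum(axis=1)


def _grid_ratio(n: int, p: int) -> float:
    return 0.01 if p >= n else 1e-4


def fit_lasso_path(
    X,
    y,
    n_lambda: int = 100,
    lambdas=None,
) -> LassoPath:
    """L1-penalized logistic path over a decreasing penalty grid.

    ``X`` is samples x candidate assays (normalized Ct values); ``y`` is the
    binary group label (patient = 1).  Constant features are dropped with a
    warning; a single-class ``y`` is an error.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise MirsigError("both classes must be present to fit a signature")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    constant = x_sd == 0
    dropped = list(X.columns[constant])
    if dropped:
        warnings.warn(f"constant features dropped: {dropped}", stacklevel=2)
        X = X.loc[:, ~constant]
        x_mean = x_mean[~constant]
        x_sd = x_sd[~constant]
    if X.shape[1] == 0:
        raise MirsigError("no non-constant candidate features remain")
    X_std = ((X - x_mean) / x_sd).to_numpy(dtype=float)
    n, p = X_std.shape
    if lambdas is None:
        lam_max = _solver.lambda_max(
            X_std[None], y[None].astype(float), np.ones((1, n))
        )[0]
        lambdas = _solver.lambda_grid(lam_max, n_lambda, _grid_ratio(n, p))[0]
    lambdas = np.asarray(sorted(np.atleast_1d(lambdas), reverse=True), dtype=float)
    coefs3, ints2 = _solver.fista_l1_logistic_path(
        X_std[None],
        y[None].astype(float),
        np.ones((1, n)),
        lambdas[None],
        tol=_SOLVER_TOL,
        max_iter=_SOLVER_MAX_ITER,
    )
    coefs = coefs3[0]
    intercepts = ints2[0]
    return LassoPath(
        feature_names=list(X.columns),
        lambdas=lambdas,
        coefs_std=coefs,
        intercepts_std=intercepts,
        x_mean=x_mean,
        x_sd=x_sd,
        X=X,
        y=y,
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# Cross-validated penalty selection (one-standard-error rule)

@dataclass
class CvResult:
    lambdas: np.ndarray
    cv_mean: np.ndarray   # per-lambda mean binomial deviance across folds
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    k: int
    seed: int


def lambda_1se_rule(lambdas, cv_mean, cv_se):
    """(lambda_min, lambda_1se): the largest penalty within one SE of the min."""
    lambdas = np.asarray(lambdas, dtype=float)
    cv_mean = np.asarray(cv_mean, dtype=float)
    cv_se = np.asarray(cv_se, dtype=float)
    i_min = int(np.argmin(cv_mean))
    cutoff = cv_mean[i_min] + cv_se[i_min]
    within = np.flatnonzero(cv_mean <= cutoff)
    i_1se = within[np.argmax(lambdas[within])]
    return float(lambdas[i_min]), float(lambdas[i_1se])


def _stratified_fold_weights(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """0/1 training-weight rows for stratified k-fold CV (k x n)."""
    counts = np.bincount(y, minlength=2)
    k_eff = int(min(k, counts.min()))
    if k_eff < 2:
        raise MirsigError("cannot build stratified folds with both classes")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    w = np.ones((k_eff, len(y)))
    for f, (_, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        w[f, te] = 0.0
    return w


def select_lambda_1se(path: LassoPath, k: int = 10, seed: int = 0) -> CvResult:
    """Stratified k-fold CV of the path; per-lambda deviance mean and SE.

    All folds are refit in one batched solver call; each fold standardizes
    with its own training statistics and is scored on the held-out samples
    by mean binomial deviance.
    """
    y = path.y.astype(float)
    X = path.X.to_numpy(dtype=float)
    w = _stratified_fold_weights(path.y, k, seed)
    k_eff = w.shape[0]
    Xf = np.broadcast_to(X, (k_eff, *X.shape))
    yf = np.broadcast_to(y, (k_eff, len(y)))
    Xs, _, _ = _solver.weighted_standardize(Xf, w)
    grids = np.broadcast_to(path.lambdas, (k_eff, len(path.lambdas)))
    coefs, intercepts = _solver.fista_l1_logistic_path(
        Xs, yf, w, grids, tol=_SOLVER_TOL, max_iter=_SOLVER_MAX_ITER
    )
    fold_dev = _solver.path_deviance(Xs, yf, 1.0 - w, coefs, intercepts)
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / math.sqrt(k_eff)
    lam_min, lam_1se = lambda_1se_rule(path.lambdas, cv_mean, cv_se)
    return CvResult(
        lambdas=path.lambdas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        k=k_eff,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Signature extraction and application

@dataclass
class SignatureModel:
    assays: list                       # ordered by |standardized coef| desc
    coefs_std: dict
    coefs_orig: dict
    intercept_std: float
    intercept_orig: float
    x_mean: dict
    x_sd: dict
    lambda_used: float | None = None
    lambda_min: float | None = None
    lambda_1se: float | None = None
    threshold: float | None = None
    meta: dict = field(default_factory=dict)

    def predict_proba(self, X_new) -> pd.Series:
        """Logistic probabilities for new samples (patient = positive class)."""
        X_new = pd.DataFrame(X_new)
        missing = [a for a in self.assays if a not in X_new.columns]
        if missing:
            raise MirsigError(f"signature assays missing from input: {missing}")
        if not self.assays:
            z = np.full(len(X_new), self.intercept_std)
        else:
            Z = np.column_stack(
                [
                    (X_new[a].to_numpy(dtype=float) - self.x_mean[a]) / self.x_sd[a]
                    for a in self.assays
                ]
            )
            coef = np.array([self.coefs_std[a] for a in self.assays])
            z = Z @ coef + self.intercept_std
        return pd.Series(1.0 / (1.0 + np.exp(-z)), index=X_new.index)

    def to_json(self, path) -> None:
        payload = {
            "assays": self.assays,
            "coefficients_standardized": self.coefs_std,
            "coefficients_original_scale": self.coefs_orig,
            "intercept_standardized": self.intercept_std,
            "intercept_original_scale": self.intercept_orig,
            "standardization_mean": self.x_mean,
            "standardization_sd": self.x_sd,
            "lambda_used": self.lambda_used,
            "lambda_min": self.lambda_min,
            "lambda_1se": self.lambda_1se,
            "threshold": self.threshold,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def extract_signature(path: LassoPath, lam: float, cv: CvResult | None = None
                      ) -> SignatureModel:
    """Signature at a penalty value (nearest grid point on the log scale)."""
    i = int(np.argmin(np.abs(np.log(path.lambdas) - np.log(lam))))
    coef = path.coefs_std[i]
    nz = np.abs(coef) > _NONZERO_TOL
    order = np.argsort(-np.abs(coef[nz]))
    names = [path.feature_names[j] for j in np.flatnonzero(nz)[order]]
    if not names:
        warnings.warn("empty signature at the requested penalty", stacklevel=2)
    coefs_std = {a: float(coef[path.feature_names.index(a)]) for a in names}
    coefs_orig = {a: coefs_std[a] / float(path.x_sd[a]) for a in names}
    intercept_std = float(path.intercepts_std[i])
    intercept_orig = intercept_std - sum(
        coefs_std[a] * float(path.x_mean[a]) / float(path.x_sd[a]) for a in names
    )
    return SignatureModel(
        assays=names,
        coefs_std=coefs_std,
        coefs_orig=coefs_orig,
        intercept_std=intercept_std,
        intercept_orig=intercept_orig,
        x_mean={a: float(path.x_mean[a]) for a in names},
        x_sd={a: float(path.x_sd[a]) for a in names},
        lambda_used=float(path.lambdas[i]),
        lambda_min=None if cv is None else cv.lambda_min,
        lambda_1se=None if cv is None else cv.lambda_1se,
        meta={"n_candidates": len(path.feature_names)},
    )


def refit_signature(X, y, assays) -> SignatureModel:
    """Unpenalized logistic refit on a fixed assay set (standardized)."""
    X = pd.DataFrame(X)[list(assays)]
    y = np.asarray(y, dtype=int)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = ((X - mu) / sd).to_numpy(dtype=float)
    coef, intercept, flagged = fit_logistic(Z, y)
    order = np.argsort(-np.abs(coef))
    names = [list(assays)[j] for j in order]
    coefs_std = {a: float(coef[list(assays).index(a)]) for a in names}
    return SignatureModel(
        assays=names,
        coefs_std=coefs_std,
        coefs_orig={a: coefs_std[a] / float(sd[a]) for a in names},
        intercept_std=float(intercept),
        intercept_orig=float(
            intercept - sum(coefs_std[a] * float(mu[a]) / float(sd[a]) for a in names)
        ),
        x_mean={a: float(mu[a]) for a in names},
        x_sd={a: float(sd[a]) for a in names},
        meta={"fit": "unpenalized refit", "ridge_fallback": flagged},
    )


def apply_signature(model: SignatureModel, X_new) -> pd.Series:
    return model.predict_proba(X_new)


# ---------------------------------------------------------------------------
# Bootstrap stability

@dataclass
class StabilityResult:
    n_bootstrap: int
    overlap_counts: np.ndarray
    overlap_frequency: float
    p_value: float   # 1 - overlap_frequency: small p = stable signature
    signature_size: int

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_bootstrap": self.n_bootstrap,
                    "signature_size": self.signature_size,
                    "overlap_frequency": self.overlap_frequency,
                    "p_value": self.p_value,
                    "overlap_counts": self.overlap_counts.tolist(),
                },
                indent=2,
            )
        )


def bootstrap_stability(
    X,
    y,
    signature,
    B: int = 10_000,
    seed: int = 0,
    n_lambda: int = 30,
    k: int = 5,
    lambda_min_ratio: float = 0.01,
    solver_tol: float = 1e-5,
    solver_max_iter: int = 300,
) -> StabilityResult:
    """Rerun the full selection on B bootstrap resamples of the cohort.

    The overlap event for a resample is recovering at least half of the
    original signature (|S_b intersect S| >= ceil(|S| / 2)); the p-value is
    one minus the event frequency.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    signature = list(signature)
    if not signature:
        raise MirsigError("bootstrap stability needs a nonempty signature")
    if B < 100:
        warnings.warn(
            f"B={B} gives a stability p-value resolution of only {1 / max(B, 1):.3g}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = len(y)
    need = math.ceil(len(signature) / 2)
    counts = np.empty(B, dtype=int)
    sig_idx = np.array([c in set(signature) for c in X.columns])
    Xarr = X.to_numpy(dtype=float)
    yarr = y.astype(float)
    ratio = lambda_min_ratio
    chunk = 200
    done = 0
    while done < B:
        bc = min(chunk, B - done)
        # resamples must keep >= 2 members of each class (both for the refit
        # and for stratified folds); short resamples are redrawn
        idxs = np.empty((bc, n), dtype=int)
        for r in range(bc):
            while True:
                idx = rng.integers(0, n, size=n)
                s = y[idx].sum()
                if 2 <= s <= n - 2:
                    break
            idxs[r] = idx
        Xb = Xarr[idxs]          # (bc, n, p)
        yb = yarr[idxs]
        ones = np.ones((bc, n))
        Xs_full, _, _ = _solver.weighted_standardize(Xb, ones)
        lam_max = _solver.lambda_max(Xs_full, yb, ones)
        grids = _solver.lambda_grid(lam_max, n_lambda, ratio)
        coefs_full, _ = _solver.fista_l1_logistic_path(
            Xs_full, yb, ones, grids, tol=solver_tol, max_iter=solver_max_iter
        )
        # stack every resample's CV folds into one batched fit
        fold_w, fold_rid = [], []
        for r in range(bc):
            wr = _stratified_fold_weights(
                yb[r].astype(int), k, int(rng.integers(2**31 - 1))
            )
            fold_w.append(wr)
            fold_rid.extend([r] * wr.shape[0])
        W = np.vstack(fold_w)
        rid = np.asarray(fold_rid)
        Xs_f, _, _ = _solver.weighted_standardize(Xb[rid], W)
        coefs_f, ints_f = _solver.fista_l1_logistic_path(
            Xs_f, yb[rid], W, grids[rid],
            tol=solver_tol, max_iter=solver_max_iter,
        )
        dev = _solver.path_deviance(Xs_f, yb[rid], 1.0 - W, coefs_f, ints_f)
        for r in range(bc):
            rows = np.flatnonzero(rid == r)
            cv_mean = dev[rows].mean(axis=0)
            cv_se = dev[rows].std(axis=0, ddof=1) / math.sqrt(len(rows))
            _, lam_1se = lambda_1se_rule(grids[r], cv_mean, cv_se)
            li = int(np.argmin(np.abs(grids[r] - lam_1se)))
            nz = np.abs(coefs_full[r, li]) > _NONZERO_TOL
            counts[done + r] = int(np.sum(nz & sig_idx))
        done += bc
    freq = float(np.mean(counts >= need))
    return StabilityResult(
        n_bootstrap=B,
        overlap_counts=counts,
        overlap_frequency=freq,
        p_value=1.0 - freq,
        signature_size=len(signature),
    )


# ---------------------------------------------------------------------------
# Random-signature null

@dataclass
class RandomNullResult:
    n_models: int
    accuracies: np.ndarray
    observed_accuracy: float
    p_value: float

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_models": self.n_models,
                    "observed_accuracy": self.observed_accuracy,
                    "p_value": self.p_value,
                    "accuracies": self.accuracies.tolist(),
                },
                indent=2,
            )
        )


def random_signature_null(
    X_train,
    y_train,
    X_test,
    y_test,
    size: int,
    observed_accuracy: float,
    pool=None,
    M: int = 1000,
    seed: int = 0,
) -> RandomNullResult:
    """Accuracy null distribution from M random assay subsets.

    Each random model is an unpenalized logistic fit on the training cohort
    over a uniformly drawn subset of ``pool`` of the given size, evaluated on
    the test cohort at its own sensitivity-first FPR-minimizing threshold --
    the same protocol as the observed signature.  The add-one rule
    p = (1 + #{acc >= observed}) / (M + 1) avoids exact zeros.
    """
    X_train = pd.DataFrame(X_train)
    X_test = pd.DataFrame(X_test)
    y_train = np.asarray(y_train, dtype=int)
    y_test = np.asarray(y_test, dtype=int)
    if pool is None:
        pool = [a for a in X_train.columns if a in X_test.columns]
    pool = list(pool)
    missing = [a for a in pool if a not in X_train.columns or a not in X_test.columns]
    if missing:
        raise MirsigError(f"pool assays absent from a cohort: {missing[:5]}")
    if size > len(pool):
        raise MirsigError(f"pool of {len(pool)} assays cannot supply {size} features")
    rng = np.random.default_rng(seed)
    subsets = np.array(
        [rng.choice(len(pool), size=size, replace=False) for _ in range(M)]
    )
    arr_tr = X_train[pool].to_numpy(dtype=float)
    arr_te = X_test[pool].to_numpy(dtype=float)
    Xb_tr = arr_tr[:, subsets].transpose(1, 0, 2)  # (M, n_train, size)
    Xb_te = arr_te[:, subsets].transpose(1, 0, 2)
    yb = np.broadcast_to(y_train.astype(float), (M, len(y_train)))
    coefs, intercepts, _ = _solver.batch_logistic_with_fallback(Xb_tr, yb)
    eta = np.einsum("pnj,pj->pn", Xb_te, coefs) + intercepts[:, None]
    all_probs = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    accs = np.empty(M)
    for mdx in range(M):
        probs = all_probs[mdx]
        thr = select_threshold_min_fpr(probs, y_test)
        accs[mdx] = confusion_metrics(probs, y_test, thr)["accuracy"]
    p = (1.0 + float(np.sum(accs >= observed_accuracy))) / (M + 1.0)
    return RandomNullResult(
        n_models=M,
        accuracies=accs,
        observed_accuracy=float(observed_accuracy),
        p_value=p,
    )
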