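"""Small logistic-regression fitting helpers shared by signature and evaluate.

Unpenalized fits fall back to a ridge-stabilized fit (small L2 penalty) when
the maximum-likelihood estimate does not exist or does not converge, e.g.
under complete separation; the fallback is flagged to the caller.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

RIDGE_C = 1000.0
_MAX_ITER = 5000
_COEF_BLOWUP = 1e4


def fit_logistic(X: np.ndarray, y: np.ndarray):
    """Unpenalized binomial logistic fit.

    Returns ``(coef, intercept, flagged)`` where ``flagged`` is True when the
    ridge-stabilized fallback was used (separation / non-convergence).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(
            C=np.inf, solver="lbfgs", tol=1e-10, max_iter=_MAX_ITER
        ).fit(X, y)
    flagged = bool(np.max(clf.n_iter_) >= _MAX_ITER) or bool(
        np.abs(clf.coef_).max() > _COEF_BLOWUP
    )
    if flagged:
        clf = LogisticRegression(
            C=RIDGE_C, solver="lbfgs", tol=1e-10, max_iter=_MAX_ITER
        ).fit(X, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0]), flagged


def predict_proba(X: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    """P(class 1) under a logistic link."""
    z = np.asarray(X, dtype=float) @ np.asarray(coef, dtype=float) + intercept
    return 1.0 / (1.0 + np.exp(-z))
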