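"""Classifier evaluation: LOOCV, ROC/PR curves, thresholds, confusion metrics.

The decision threshold follows the sensitivity-first convention used for
diagnostic signatures: among all candidate thresholds, maximize the true
positive rate, then minimize the false positive rate, then prefer the larger
threshold.  (Literal FPR minimization alone is degenerate -- the
always-negative classifier has FPR 0 -- and is available as ``rule="literal"``
for comparison.)  Predictions use ``probability >= threshold``.

AUC-ROC is the trapezoidal area (equal to the Mann-Whitney statistic with
half credit for ties) with a DeLong 95% confidence interval; AUC-PR is the
trapezoidal area over recall with a stratified-bootstrap interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import _solver
from .data import MirsigError


# ---------------------------------------------------------------------------
# LOOCV

def loocv_probabilities(X, y, signature_assays=None):
    """Held-out probability for every sample via n leave-one-out refits.

    The logistic coefficients are refit on each n-1 subset; the feature set
    is fixed (selection is not redone).  Returns ``(probs, n_flagged)`` where
    ``n_flagged`` counts folds that needed the ridge-stabilized fallback.
    """
    X = pd.DataFrame(X)
    if signature_assays is not None:
        X = X[list(signature_assays)]
    y = np.asarray(y, dtype=int)
    n = len(X)
    if n < 4:
        raise MirsigError("LOOCV needs at least 4 samples")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise MirsigError("a LOOCV training fold lost one class entirely")
    arr = X.to_numpy(dtype=float)
    # all n leave-one-out refits as one batched weighted fit
    Xb = np.broadcast_to(arr, (n, *arr.shape))
    yb = np.broadcast_to(y.astype(float), (n, n))
    w = 1.0 - np.eye(n)
    coefs, intercepts, flagged = _solver.batch_logistic_with_fallback(Xb, yb, w)
    eta = np.einsum("ij,ij->i", arr, coefs) + intercepts
    probs = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    return pd.Series(probs, index=X.index), int(flagged.sum())


# ---------------------------------------------------------------------------
# ROC with DeLong CI

@dataclass
class RocResult:
    points: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float
    ci: tuple[float, float]


def _delong_ci(probs, y, level: float = 0.95):
    """DeLong variance of the AUC via structural components."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = probs[y == 1]
    neg = probs[y == 0]
    m, n = len(pos), len(neg)
    r_all = rankdata(np.concatenate([pos, neg]))
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (r_all[:m] - r_pos) / n       # per-positive placement
    v10 = 1.0 - (r_all[m:] - r_neg) / m  # per-negative placement
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))


def roc_metrics(probs, y) -> RocResult:
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise MirsigError("ROC needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(y, probs)
    auc, ci = _delong_ci(probs, y)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return RocResult(points=points, auc=auc, ci=ci)


# ---------------------------------------------------------------------------
# PR with bootstrap CI

@dataclass
class PrResult:
    points: pd.DataFrame  # columns recall, precision, threshold
    auc: float
    ci: tuple[float, float]
    n_boot: int = 0


def _pr_points(probs: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Precision-recall at every unique threshold, anchored at recall 0."""
    n_pos = int(y.sum())
    rows = []
    for t in np.unique(probs)[::-1]:
        pred = probs >= t
        tp = int((pred & (y == 1)).sum())
        rows.append((tp / n_pos, tp / int(pred.sum()), t))
    first_precision = rows[0][1]
    pts = pd.DataFrame(rows, columns=["recall", "precision", "threshold"])
    anchor = pd.DataFrame(
        [[0.0, first_precision, np.inf]], columns=pts.columns
    )
    pts = pd.concat([anchor, pts], ignore_index=True)
    return pts.sort_values(["recall", "threshold"], ascending=[True, False])


def _pr_auc(probs: np.ndarray, y: np.ndarray) -> float:
    pts = _pr_points(probs, y)
    return float(np.trapezoid(pts["precision"].to_numpy(), pts["recall"].to_numpy()))


def pr_metrics(probs, y, n_boot: int = 2000, seed: int = 0) -> PrResult:
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.sum() == 0:
        raise MirsigError("PR curve needs at least one positive sample")
    points = _pr_points(probs, y)
    auc = float(np.trapezoid(points["precision"].to_numpy(),
                             points["recall"].to_numpy()))
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        boot[b] = _pr_auc(probs[idx], y[idx])
    ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))
    return PrResult(points=points, auc=auc, ci=ci, n_boot=n_boot)


# ---------------------------------------------------------------------------
# Threshold selection and confusion metrics

def _candidate_thresholds(probs: np.ndarray) -> np.ndarray:
    u = np.unique(probs)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.empty(0)
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _rates(probs, y, threshold):
    pred = probs >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    return tpr, fpr


def select_threshold_min_fpr(probs, y, rule: str = "tpr_first") -> float:
    """FPR-minimizing decision threshold.

    ``tpr_first`` (default): maximize TPR, then minimize FPR, then prefer the
    larger threshold -- keeps sensitivity at its maximum while pushing false
    positives down.  ``literal``: minimize FPR outright (degenerate: selects
    the always-negative classifier whenever probabilities overlap).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    best = None
    for t in _candidate_thresholds(probs):
        tpr, fpr = _rates(probs, y, t)
        key = (tpr, -fpr, t) if rule == "tpr_first" else (-fpr, t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


UNDEFINED = None  # marker for zero-denominator rates


def confusion_metrics(probs, y, threshold: float) -> dict:
    """Accuracy, sensitivity, specificity, PPV and NPV at a threshold.

    Samples with probability >= threshold are predicted patients.  Rates
    with a zero denominator are reported as ``None``, never silent NaN.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    pred = probs >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())

    def safe(num, den):
        return num / den if den else UNDEFINED

    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "accuracy": safe(tp + tn, tp + fp + tn + fn),
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "positive_prediction_rate": safe(tp, tp + fp),
        "negative_prediction_rate": safe(tn, tn + fn),
        "threshold": float(threshold),
    }


# ---------------------------------------------------------------------------
# Cohort-level reports

@dataclass
class EvalReport:
    probabilities: pd.Series
    roc: RocResult
    pr: PrResult
    threshold: float
    metrics: dict
    metrics_at_fixed_threshold: dict | None = None
    n_flagged_fits: int = 0
    notes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "probabilities": self.probabilities.round(10).to_dict(),
            "auc_roc": self.roc.auc,
            "auc_roc_ci": list(self.roc.ci),
            "auc_pr": self.pr.auc,
            "auc_pr_ci": list(self.pr.ci),
            "threshold": self.threshold,
            "metrics": self.metrics,
            "metrics_at_fixed_threshold": self.metrics_at_fixed_threshold,
            "n_flagged_fits": self.n_flagged_fits,
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def write_curves(self, roc_path, pr_path) -> None:
        self.roc.points.to_csv(roc_path, index=False)
        self.pr.points.to_csv(pr_path, index=False)


def evaluate_probabilities(
    probs, y, threshold: float | None = None, n_boot: int = 2000, seed: int = 0
) -> EvalReport:
    """Full metric block for a set of probabilities and labels."""
    probs = pd.Series(probs)
    y = np.asarray(y, dtype=int)
    chosen = (
        select_threshold_min_fpr(probs.to_numpy(), y)
        if threshold is None
        else float(threshold)
    )
    return EvalReport(
        probabilities=probs,
        roc=roc_metrics(probs.to_numpy(), y),
        pr=pr_metrics(probs.to_numpy(), y, n_boot=n_boot, seed=seed),
        threshold=chosen,
        metrics=confusion_metrics(probs.to_numpy(), y, chosen),
    )


def evaluate_loocv(X, y, signature_assays=None, n_boot: int = 2000, seed: int = 0):
    """LOOCV probabilities plus the full evaluation report."""
    probs, n_flagged = loocv_probabilities(X, y, signature_assays)
    report = evaluate_probabilities(probs, y, n_boot=n_boot, seed=seed)
    report.n_flagged_fits = n_flagged
    return report


def evaluate_on_cohort(
    model,
    X_new,
    y_new,
    recalibrate_threshold: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalReport:
    """Apply a fitted signature model to a new cohort.

    When ``recalibrate_threshold`` is set, the decision threshold is
    re-selected on the new cohort (the ad hoc cohort-specific threshold);
    the metric block at the model's stored threshold is reported alongside.
    """
    probs = model.predict_proba(X_new)
    y_new = np.asarray(y_new, dtype=int)
    stored = getattr(model, "threshold", None)
    if recalibrate_threshold or stored is None:
        report = evaluate_probabilities(probs, y_new, n_boot=n_boot, seed=seed)
        if stored is not None:
            report.metrics_at_fixed_threshold = confusion_metrics(
                probs.to_numpy(), y_new, stored
            )
            report.notes.append("threshold recalibrated on this cohort")
    else:
        report = evaluate_probabilities(
            probs, y_new, threshold=stored, n_boot=n_boot, seed=seed
        )
        report.notes.append("model's stored threshold reused")
    return report
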