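"""LOOCV, ROC/PR curves, threshold selection and confusion metrics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mirsig import (
    confusion_metrics,
    evaluate_on_cohort,
    loocv_probabilities,
    pr_metrics,
    roc_metrics,
    select_threshold_min_fpr,
)
from mirsig.data import MirsigError
from mirsig.evaluate import evaluate_probabilities
from mirsig.signature import refit_signature


class TestLoocv:
    def test_one_probability_per_sample(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (12, 2)), columns=["a", "b"])
        y = np.array([1, 0] * 6)
        probs, _ = loocv_probabilities(X, y)
        assert len(probs) == 12
        assert probs.index.equals(X.index)

    def test_matches_statsmodels_refits(self):
        """Brute-force oracle: n independent GLM fits on the n-1 subsets."""
        rng = np.random.default_rng(1)
        n = 30
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        y = (rng.random(n) < 1 / (1 + np.exp(-X["a"].to_numpy()))).astype(int)
        probs, flagged = loocv_probabilities(X, y)
        assert flagged == 0
        Xc = sm.add_constant(X.to_numpy())
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            fit = sm.GLM(y[mask], Xc[mask], family=sm.families.Binomial()).fit()
            oracle = float(fit.predict(Xc[i : i + 1])[0])
            assert probs.iloc[i] == pytest.approx(oracle, abs=1e-6)

    def test_separable_feature_held_out_correct_side(self):
        y = np.array([1] * 8 + [0] * 8)
        X = pd.DataFrame({"f": 25.0 - 5.0 * y + np.linspace(-0.4, 0.4, 16)})
        probs, flagged = loocv_probabilities(X, y)
        assert flagged > 0  # separation triggers the ridge-stabilized path
        assert ((probs > 0.5).astype(int).to_numpy() == y).all()

    def test_lost_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0]})
        with pytest.raises(MirsigError, match="class"):
            loocv_probabilities(X, np.array([1, 0, 0, 0, 0]))


class TestRoc:
    def test_perfect_ranking_auc_one(self):
        y = np.array([0, 0, 1, 1])
        assert roc_metrics(np.array([0.1, 0.2, 0.8, 0.9]), y).auc == 1.0

    def test_all_ties_auc_half(self):
        y = np.array([0, 1, 0, 1])
        assert roc_metrics(np.full(4, 0.5), y).auc == 0.5

    def test_auc_equals_pairwise_mann_whitney(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
            probs = rng.choice(np.linspace(0, 1, 7), size=n)  # forces ties
            res = roc_metrics(probs, y)
            pos, neg = probs[y == 1], probs[y == 0]
            pairs = [
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos for q in neg
            ]
            assert res.auc == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_label_flip_reflects_auc(self):
        rng = np.random.default_rng(3)
        probs = rng.random(30)
        y = (rng.random(30) < 0.5).astype(int)
        if y.sum() in (0, 30):
            y[0] = 1 - y[0]
        a = roc_metrics(probs, y).auc
        b = roc_metrics(probs, 1 - y).auc
        assert a == pytest.approx(1.0 - b)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        probs = rng.random(40)
        y = (rng.random(40) < 0.4).astype(int)
        a = roc_metrics(probs, y).auc
        b = roc_metrics(1 / (1 + np.exp(-5 * probs)), y).auc
        assert a == pytest.approx(b)

    def test_delong_ci_contains_auc_and_shrinks(self):
        rng = np.random.default_rng(5)

        def width(n):
            y = np.array([1] * (n // 2) + [0] * (n // 2))
            probs = np.clip(0.5 + 0.25 * (2 * y - 1) + rng.normal(0, 0.25, n), 0, 1)
            res = roc_metrics(probs, y)
            assert res.ci[0] <= res.auc <= res.ci[1]
            return res.ci[1] - res.ci[0]

        assert width(200) < width(20)

    def test_single_class_rejected(self):
        with pytest.raises(MirsigError):
            roc_metrics(np.array([0.2, 0.4]), np.array([1, 1]))


def pr_auc_oracle(probs, y):
    """Trapezoid over recall at every unique threshold, anchored at recall 0."""
    pts = []
    for t in sorted(set(probs), reverse=True):
        pred = probs >= t
        tp = int((pred & (y == 1)).sum())
        pts.append((tp / y.sum(), tp / pred.sum()))
    pts = [(0.0, pts[0][1])] + pts
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts[:-1], pts[1:]):
        area += (r1 - r0) * (p0 + p1) / 2.0
    return area


class TestPr:
    def test_perfect_ranking_auc_one(self):
        y = np.array([0, 0, 1, 1])
        res = pr_metrics(np.array([0.1, 0.2, 0.8, 0.9]), y, n_boot=50)
        assert res.auc == pytest.approx(1.0)

    def test_all_ties_auc_prevalence(self):
        y = np.array([1, 0, 0, 1, 0])
        res = pr_metrics(np.full(5, 0.3), y, n_boot=50)
        assert res.auc == pytest.approx(0.4)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            y = np.array([1, 1, 0, 0, 1, 0])
            probs = rng.choice(np.linspace(0.1, 0.9, 5), size=6)
            res = pr_metrics(probs, y, n_boot=10)
            assert res.auc == pytest.approx(pr_auc_oracle(probs, y), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(MirsigError):
            pr_metrics(np.array([0.1, 0.9]), np.array([0, 0]))

    def test_bootstrap_ci_brackets_auc_for_noisy_scores(self):
        rng = np.random.default_rng(7)
        y = np.array([1] * 20 + [0] * 20)
        probs = np.clip(0.5 + 0.2 * (2 * y - 1) + rng.normal(0, 0.3, 40), 0, 1)
        res = pr_metrics(probs, y, n_boot=500, seed=1)
        assert res.ci[0] <= res.auc <= res.ci[1]


class TestThreshold:
    def test_separable_reaches_tpr1_fpr0(self):
        y = np.array([0, 0, 1, 1])
        probs = np.array([0.1, 0.2, 0.7, 0.9])
        t = select_threshold_min_fpr(probs, y)
        m = confusion_metrics(probs, y, t)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_overlapping_example_enumerated(self):
        # ctl: 0.1, 0.6; pat: 0.4, 0.9 -> TPR-max requires t <= 0.4; the
        # FPR-minimal such threshold sits in (0.1, 0.4): TPR 1, FPR 0.5
        probs = np.array([0.1, 0.6, 0.4, 0.9])
        y = np.array([0, 0, 1, 1])
        t = select_threshold_min_fpr(probs, y)
        assert 0.1 < t < 0.4
        m = confusion_metrics(probs, y, t)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.5

    def test_all_identical_probs_predicts_everyone_positive(self):
        probs = np.full(6, 0.4)
        y = np.array([1, 0, 1, 0, 1, 0])
        t = select_threshold_min_fpr(probs, y)
        m = confusion_metrics(probs, y, t)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_literal_rule_degenerates_to_always_negative(self):
        probs = np.array([0.1, 0.6, 0.4, 0.9])
        y = np.array([0, 0, 1, 1])
        t = select_threshold_min_fpr(probs, y, rule="literal")
        m = confusion_metrics(probs, y, t)
        assert m["specificity"] == 1.0 and m["sensitivity"] == 0.0


class TestConfusionMetrics:
    def test_perfect_confusion_matrix(self):
        probs = np.array([0.9] * 10 + [0.1] * 12)
        y = np.array([1] * 10 + [0] * 12)
        m = confusion_metrics(probs, y, 0.5)
        for key in ("accuracy", "sensitivity", "specificity",
                    "positive_prediction_rate", "negative_prediction_rate"):
            assert m[key] == 1.0

    def test_zero_denominator_reported_undefined(self):
        probs = np.array([0.1, 0.2])
        y = np.array([0, 0])
        m = confusion_metrics(probs, y, 0.5)
        assert m["positive_prediction_rate"] is None
        assert m["sensitivity"] is None

    def test_external_cohort_style_counts(self):
        # TP=35, FP=10, TN=10, FN=0: sensitivity 1.00, specificity 0.50,
        # accuracy 45/55
        probs = np.concatenate([np.full(35, 0.8), np.full(10, 0.8),
                                np.full(10, 0.2)])
        y = np.concatenate([np.ones(35, int), np.zeros(20, int)])
        m = confusion_metrics(probs, y, 0.5)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.5
        assert m["accuracy"] == pytest.approx(45 / 55)
        assert m["positive_prediction_rate"] == pytest.approx(35 / 45)

    def test_matches_direct_counting_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            probs = rng.random(n)
            y = (rng.random(n) < 0.5).astype(int)
            t = float(rng.random())
            m = confusion_metrics(probs, y, t)
            pred = probs >= t
            tp = np.sum(pred & (y == 1))
            fp = np.sum(pred & (y == 0))
            tn = np.sum(~pred & (y == 0))
            fn = np.sum(~pred & (y == 1))
            assert (m["tp"], m["fp"], m["tn"], m["fn"]) == (tp, fp, tn, fn)
            if tp + fn:
                assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m["specificity"] == pytest.approx(tn / (tn + fp))
            assert m["accuracy"] == pytest.approx((tp + tn) / n)


class TestEvaluateOnCohort:
    def _model_and_data(self, seed=9, n=40, shift=2.0):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        X = pd.DataFrame(
            {
                "a": 25.0 - shift * y + rng.normal(0, 1.0, n),
                "b": 26.0 + shift * y + rng.normal(0, 1.0, n),
            }
        )
        model = refit_signature(X, y, ["a", "b"])
        return model, X, y

    def test_training_cohort_consistency(self):
        model, X, y = self._model_and_data()
        probs = model.predict_proba(X)
        base = evaluate_probabilities(probs, y, n_boot=100)
        model.threshold = base.threshold
        rep = evaluate_on_cohort(model, X, y, recalibrate_threshold=False,
                                 n_boot=100)
        assert rep.threshold == base.threshold
        assert rep.metrics == base.metrics
        assert rep.roc.auc == base.roc.auc

    def test_recalibrated_accuracy_not_worse_on_shifted_cohort(self):
        model, X, y = self._model_and_data(seed=10)
        probs = model.predict_proba(X)
        model.threshold = evaluate_probabilities(probs, y, n_boot=50).threshold
        rng = np.random.default_rng(11)
        n2 = 60
        y2 = np.array([1] * 45 + [0] * 15)  # shifted prevalence
        X2 = pd.DataFrame(
            {
                "a": 24.0 - 2.0 * y2 + rng.normal(0, 1.2, n2),
                "b": 27.0 + 2.0 * y2 + rng.normal(0, 1.2, n2),
            }
        )
        recal = evaluate_on_cohort(model, X2, y2, recalibrate_threshold=True,
                                   n_boot=50)
        fixed = recal.metrics_at_fixed_threshold
        assert recal.metrics["sensitivity"] == 1.0  # rule keeps TPR maximal
        assert recal.metrics["accuracy"] >= fixed["accuracy"] - 1e-12 or (
            fixed["sensitivity"] < 1.0
        )

    def test_label_permuted_cohort_near_chance(self):
        model, X, y = self._model_and_data(seed=12)
        rng = np.random.default_rng(13)
        yperm = rng.permutation(y)
        rep = evaluate_on_cohort(model, X, yperm, n_boot=50)
        assert 0.35 <= rep.roc.auc <= 0.65
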