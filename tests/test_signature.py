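"""LASSO signature selection, stability bootstrap and random-signature null."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from mirsig import (
    apply_signature,
    bootstrap_stability,
    extract_signature,
    fit_lasso_path,
    random_signature_null,
    refit_signature,
    select_lambda_1se,
)
from mirsig.data import MirsigError
from mirsig.signature import SignatureModel, lambda_1se_rule


def _planted(seed=0, n_pat=16, n_ctl=22, n_noise=6, effect=3.0, noise=0.5):
    """Ct-style design matrix with planted group-differential features."""
    rng = np.random.default_rng(seed)
    n = n_pat + n_ctl
    y = np.array([1] * n_pat + [0] * n_ctl)
    offsets = rng.normal(0, 0.5, n)
    cols = {}
    for j, eff in enumerate([effect, effect, effect, -effect]):
        base = rng.uniform(22, 27)
        cols[f"sig{j}"] = base - eff * y + offsets + rng.normal(0, noise, n)
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.uniform(22, 27) + offsets + rng.normal(0, noise, n)
    return pd.DataFrame(cols), y


class TestLassoPath:
    def test_lambda_max_gives_empty_model(self):
        X, y = _planted(seed=1)
        path = fit_lasso_path(X, y, n_lambda=30)
        assert path.n_nonzero[0] == 0
        model = extract_signature(path, 2 * path.lambdas[0])
        assert model.assays == []

    def test_sparsity_monotone_along_path(self):
        # independent features: no active-set exchanges, so the number of
        # nonzero coefficients can only grow as the penalty relaxes.
        # (correlated designs can genuinely drop a variable mid-path; that
        # behavior matches liblinear and is not an invariant of the lasso)
        rng = np.random.default_rng(2)
        n = 60
        y = np.array([1] * 30 + [0] * 30)
        X = pd.DataFrame(
            {
                f"f{j}": 25.0 - (0.5 + 0.5 * j) * y + rng.normal(0, 1.0, n)
                for j in range(5)
            }
        )
        path = fit_lasso_path(X, y, n_lambda=60)
        assert (np.diff(path.n_nonzero) >= 0).all()

    def test_separating_feature_dominates(self):
        rng = np.random.default_rng(3)
        n = 200
        y = np.array([1] * 100 + [0] * 100)
        X = pd.DataFrame(
            {"sep": 25.0 - 3.0 * y + rng.normal(0, 0.3, n)}
            | {f"noise{j}": rng.normal(25, 1, n) for j in range(5)}
        )
        path = fit_lasso_path(X, y, n_lambda=40)
        coefs = path.coefs_std[-5]  # a small but not extreme penalty
        assert path.feature_names[int(np.argmax(np.abs(coefs)))] == "sep"

    def test_duplicated_feature_prediction_equivalent(self):
        X, y = _planted(seed=4, n_noise=3)
        Xdup = X.copy()
        Xdup["sig0_copy"] = X["sig0"]
        path1 = fit_lasso_path(X, y, n_lambda=20)
        grid = path1.lambdas
        path2 = fit_lasso_path(Xdup, y, lambdas=grid)
        i = 10
        z1 = (
            ((X - path1.x_mean) / path1.x_sd).to_numpy() @ path1.coefs_std[i]
            + path1.intercepts_std[i]
        )
        z2 = (
            ((Xdup - path2.x_mean) / path2.x_sd).to_numpy() @ path2.coefs_std[i]
            + path2.intercepts_std[i]
        )
        p1 = 1 / (1 + np.exp(-z1))
        p2 = 1 / (1 + np.exp(-z2))
        assert np.abs(p1 - p2).max() < 1e-6

    def test_matches_liblinear_oracle(self):
        """Independent solver check: coefficients agree with scikit-learn's
        liblinear L1 logistic fit at matched penalties."""
        X, y = _planted(seed=5)
        path = fit_lasso_path(X, y, n_lambda=20)
        Xs = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        n = len(y)
        for i in (4, 9, 14):
            lam = path.lambdas[i]
            clf = LogisticRegression(
                l1_ratio=1,
                C=1.0 / (n * lam),
                solver="liblinear",
                intercept_scaling=1000.0,  # liblinear penalizes the intercept;
                tol=1e-10,                 # large scaling approximates ours
                max_iter=20000,
            ).fit(Xs, y)
            assert np.abs(clf.coef_.ravel() - path.coefs_std[i]).max() < 1e-2

    def test_feature_scaling_leaves_probabilities_unchanged(self):
        X, y = _planted(seed=6)
        Xscaled = X.copy()
        Xscaled["sig0"] = X["sig0"] * 10.0
        p1 = fit_lasso_path(X, y, n_lambda=15)
        p2 = fit_lasso_path(Xscaled, y, n_lambda=15)
        assert np.allclose(p1.lambdas, p2.lambdas)
        assert np.allclose(p1.coefs_std, p2.coefs_std, atol=1e-6)

    def test_constant_feature_dropped_with_warning(self):
        X, y = _planted(seed=7, n_noise=2)
        X["flat"] = 25.0
        with pytest.warns(UserWarning, match="constant features"):
            path = fit_lasso_path(X, y, n_lambda=10)
        assert "flat" not in path.feature_names
        assert path.dropped_features == ["flat"]

    def test_single_class_rejected(self):
        X, _ = _planted(seed=8)
        with pytest.raises(MirsigError, match="both classes"):
            fit_lasso_path(X, np.ones(len(X), dtype=int))


class TestLambdaSelection:
    def test_one_se_rule_forced_example(self):
        lam_min, lam_1se = lambda_1se_rule(
            [1.0, 0.1, 0.01], [0.5, 0.2, 0.3], [0.1, 0.05, 0.1]
        )
        assert lam_min == 0.1
        assert lam_1se == 0.1  # 0.5 > 0.25 at lambda=1

    def test_zero_se_degenerates_to_lambda_min(self):
        lam_min, lam_1se = lambda_1se_rule(
            [1.0, 0.1, 0.01], [0.5, 0.3, 0.2], [0.0, 0.0, 0.0]
        )
        assert lam_1se == lam_min == 0.01

    def test_same_seed_same_folds_and_choice(self):
        X, y = _planted(seed=9)
        path = fit_lasso_path(X, y, n_lambda=25)
        cv1 = select_lambda_1se(path, k=5, seed=3)
        cv2 = select_lambda_1se(path, k=5, seed=3)
        assert cv1.lambda_1se == cv2.lambda_1se
        assert np.allclose(cv1.cv_mean, cv2.cv_mean)

    def test_lambda_1se_not_below_lambda_min(self):
        X, y = _planted(seed=10)
        path = fit_lasso_path(X, y, n_lambda=25)
        cv = select_lambda_1se(path, k=5, seed=0)
        assert cv.lambda_1se >= cv.lambda_min


class TestSignatureModel:
    def test_assays_ordered_by_coefficient_magnitude(self):
        X, y = _planted(seed=11)
        path = fit_lasso_path(X, y, n_lambda=30)
        model = extract_signature(path, path.lambdas[-5])
        mags = [abs(model.coefs_std[a]) for a in model.assays]
        assert mags == sorted(mags, reverse=True)

    def test_empty_signature_warns_but_returns(self):
        X, y = _planted(seed=12)
        path = fit_lasso_path(X, y, n_lambda=10)
        with pytest.warns(UserWarning, match="empty signature"):
            model = extract_signature(path, path.lambdas[0])
        assert model.assays == []

    def test_null_model_probability_half(self):
        model = SignatureModel(
            assays=[], coefs_std={}, coefs_orig={}, intercept_std=0.0,
            intercept_orig=0.0, x_mean={}, x_sd={},
        )
        probs = model.predict_proba(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(probs, 0.5)

    def test_single_coefficient_at_standardized_zero(self):
        model = SignatureModel(
            assays=["a"], coefs_std={"a": 4.03}, coefs_orig={"a": 4.03},
            intercept_std=0.0, intercept_orig=0.0, x_mean={"a": 25.0},
            x_sd={"a": 1.0},
        )
        probs = model.predict_proba(pd.DataFrame({"a": [25.0]}))
        assert probs.iloc[0] == pytest.approx(0.5)

    def test_manual_linear_predictor_oracle(self):
        model = SignatureModel(
            assays=["a", "b"],
            coefs_std={"a": -1.24, "b": 4.03},
            coefs_orig={},
            intercept_std=0.7,
            intercept_orig=0.0,
            x_mean={"a": 25.0, "b": 28.0},
            x_sd={"a": 2.0, "b": 0.5},
        )
        X = pd.DataFrame({"a": [24.0, 25.0, 30.0], "b": [28.5, 27.0, 28.0]})
        probs = model.predict_proba(X)
        for i in range(3):
            z = (
                0.7
                + -1.24 * (X["a"].iloc[i] - 25.0) / 2.0
                + 4.03 * (X["b"].iloc[i] - 28.0) / 0.5
            )
            assert probs.iloc[i] == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-12)

    def test_missing_assay_raises_with_names(self):
        X, y = _planted(seed=13)
        path = fit_lasso_path(X, y, n_lambda=30)
        model = extract_signature(path, path.lambdas[-1])
        with pytest.raises(MirsigError, match=model.assays[0]):
            apply_signature(model, pd.DataFrame({"other": [1.0]}))

    def test_refit_signature_unpenalized(self):
        X, y = _planted(seed=14)
        model = refit_signature(X, y, ["sig0", "sig3"])
        assert set(model.assays) == {"sig0", "sig3"}
        probs = model.predict_proba(X)
        # planted effects are strong: the refit separates the groups
        assert ((probs > 0.5).astype(int) == y).mean() > 0.9


class TestBootstrapStability:
    def test_strong_signal_perfectly_stable(self):
        X, y = _planted(seed=15, effect=6.0, noise=0.1, n_noise=2)
        sig = ["sig0", "sig1", "sig2", "sig3"]
        res = bootstrap_stability(X, y, sig, B=100, seed=0)
        assert res.overlap_frequency == 1.0
        assert res.p_value == 0.0
        assert (res.overlap_counts >= 2).all()

    def test_pure_noise_unstable(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.normal(25, 1, (38, 8)),
                         columns=[f"n{j}" for j in range(8)])
        y = np.array([1] * 16 + [0] * 22)
        res = bootstrap_stability(X, y, ["n0", "n1", "n2", "n3"], B=150, seed=1)
        assert res.p_value > 0.5

    def test_small_b_warns(self):
        X, y = _planted(seed=17, n_noise=0)
        with pytest.warns(UserWarning, match="resolution"):
            bootstrap_stability(X, y, ["sig0", "sig1"], B=20, seed=0)

    def test_empty_signature_rejected(self):
        X, y = _planted(seed=18)
        with pytest.raises(MirsigError, match="nonempty"):
            bootstrap_stability(X, y, [], B=100)


class TestRandomNull:
    def _data(self, seed=19, n_tr=30, n_te=40, p=12):
        rng = np.random.default_rng(seed)
        cols = [f"f{j}" for j in range(p)]
        Xtr = pd.DataFrame(rng.normal(25, 1, (n_tr, p)), columns=cols)
        Xte = pd.DataFrame(rng.normal(25, 1, (n_te, p)), columns=cols)
        ytr = np.array([1] * (n_tr // 2) + [0] * (n_tr - n_tr // 2))
        yte = np.array([1] * (n_te // 2) + [0] * (n_te - n_te // 2))
        return Xtr, ytr, Xte, yte

    def test_observed_above_all_gives_add_one_p(self):
        Xtr, ytr, Xte, yte = self._data()
        res = random_signature_null(
            Xtr, ytr, Xte, yte, size=3, observed_accuracy=1.01, M=50, seed=0
        )
        assert res.p_value == pytest.approx(1.0 / 51.0)

    def test_degenerate_pool_p_one(self):
        Xtr, ytr, Xte, yte = self._data()
        pool = ["f0", "f1", "f2"]
        # every random draw is the full pool: all accuracies equal the
        # observed model's accuracy, so p = (1 + M) / (M + 1) = 1
        first = random_signature_null(
            Xtr, ytr, Xte, yte, size=3, pool=pool,
            observed_accuracy=0.0, M=1, seed=0,
        )
        res = random_signature_null(
            Xtr, ytr, Xte, yte, size=3, pool=pool,
            observed_accuracy=float(first.accuracies[0]), M=20, seed=1,
        )
        assert res.p_value == 1.0

    def test_pool_too_small_rejected(self):
        Xtr, ytr, Xte, yte = self._data()
        with pytest.raises(MirsigError, match="pool"):
            random_signature_null(
                Xtr, ytr, Xte, yte, size=5, pool=["f0"],
                observed_accuracy=0.5, M=10,
            )
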