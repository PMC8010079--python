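"""Responder stratification, stepwise selection, ridge logistic, LOSO, transfer."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import refeedomics.predict as pred
from refeedomics.predict import (
    ResponderRule,
    classification_metrics,
    fit_ridge_logistic,
    forward_stepwise_select,
    loso_cv_predict,
    ridge_logistic_objective,
    stratify_responders,
    transfer_predict,
)
from refeedomics.simulate import simulate_prediction_dataset


class TestResponderRule:
    @pytest.mark.parametrize(
        "dsbp,dmed,expected",
        [
            (-8.0, 0.0, "responder"),  # clear BP drop, medication unchanged
            (5.0, 0.0, "non-responder"),
            (-1.0, -1.0, "responder"),  # medication-reduction branch
            (-1.0, 0.0, "non-responder"),  # small drop, no med change
            (-8.0, 0.5, "non-responder"),  # drop achieved only by adding drugs
        ],
    )
    def test_default_rule(self, dsbp, dmed, expected):
        assert ResponderRule().classify(dsbp, dmed) == expected

    def test_stratify_excludes_missing_visit(self):
        meta = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b"],
                "visit": ["V1", "V3", "V1"],
                "sbp_24h": [130.0, 120.0, 140.0],
            }
        )
        labels = stratify_responders(meta, None)
        assert list(labels["subject_id"]) == ["a"]
        assert labels["label"].iloc[0] == "responder"


class TestRidgeLogistic:
    def test_zero_design_gives_zero_weights(self):
        w = fit_ridge_logistic(np.zeros((6, 2)), [0, 1, 0, 1, 0, 1])
        assert np.allclose(w, 0.0)

    def test_weights_vanish_as_c_to_zero(self, rng):
        X = rng.normal(size=(20, 3))
        y = (rng.random(20) < 0.5).astype(int)
        norms = [np.linalg.norm(fit_ridge_logistic(X, y, c)) for c in (1.0, 1e-2, 1e-4)]
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 1e-3

    def test_1d_matches_golden_section(self, rng):
        for _ in range(10):
            X = rng.normal(size=(15, 1))
            y = (rng.random(15) < 0.5).astype(int)
            if len(np.unique(y)) < 2:
                continue
            w = fit_ridge_logistic(X, y, 1.0)[0]
            res = optimize.minimize_scalar(
                lambda v: ridge_logistic_objective([v], X, y, 1.0),
                bracket=(-5, 0, 5),
                method="golden",
                options={"xtol": 1e-12},
            )
            assert w == pytest.approx(res.x, abs=1e-6)

    def test_gradient_norm_at_solution(self, rng):
        X = rng.normal(size=(25, 4))
        y = (X[:, 0] + rng.normal(size=25) > 0).astype(int)
        w = fit_ridge_logistic(X, y, 1.0)
        # gradient of the 1/C-scaled objective used by the solver
        sy = np.where(y > 0, 1.0, -1.0)
        mu = 1.0 / (1.0 + np.exp(sy * (X @ w)))
        grad = -(X * (sy * mu)[:, None]).sum(axis=0) + w
        assert np.linalg.norm(grad) <= 1e-8

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fit_ridge_logistic(np.array([[np.nan]]), [1])


def single_feature_lrt_p_bruteforce(Z, y, j, micro_ridge=1e-6):
    """Independent oracle: scalar-optimized single-feature logistic LRT."""
    xj = Z[:, j]
    sy = np.where(y > 0, 1.0, -1.0)

    def negll(w):
        return np.logaddexp(0.0, -sy * (xj * w)).sum() + 0.5 * micro_ridge * w**2

    res = optimize.minimize_scalar(negll, bounds=(-50, 50), method="bounded",
                                   options={"xatol": 1e-10})
    ll_full = -np.logaddexp(0.0, -sy * (xj * res.x)).sum()
    ll_null = -len(y) * np.log(2.0)
    return stats.chi2.sf(max(2 * (ll_full - ll_null), 0.0), 1)


class TestStepwise:
    def test_k_zero_empty_path(self, rng):
        path = forward_stepwise_select(rng.normal(size=(10, 5)), [0, 1] * 5, k=0)
        assert path.features == []

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            forward_stepwise_select(rng.normal(size=(10, 3)), [0, 1] * 5, k=4)

    def test_signal_feature_selected_first(self, rng):
        y = np.array([0, 1] * 16)
        X = rng.normal(size=(32, 100))
        X[:, 57] = y * 2.0 - 1.0 + rng.normal(0, 0.3, 32)
        path = forward_stepwise_select(X, y, k=3)
        assert path.features[0] == 57

    def test_first_step_matches_bruteforce_argmin(self, rng):
        for trial in range(5):
            y = (rng.random(20) < 0.5).astype(int)
            if len(np.unique(y)) < 2:
                continue
            Z = rng.normal(size=(20, 15))
            Z = (Z - Z.mean(0)) / Z.std(0)
            path = forward_stepwise_select(Z, y, k=1)
            oracle_ps = [single_feature_lrt_p_bruteforce(Z, y, j) for j in range(15)]
            assert path.features[0] == int(np.argmin(oracle_ps))
            assert path.p_values[0] == pytest.approx(min(oracle_ps), abs=1e-5)

    def test_deterministic_path(self, rng):
        X = rng.normal(size=(24, 40))
        y = (rng.random(24) < 0.5).astype(int)
        p1 = forward_stepwise_select(X, y, k=5).features
        p2 = forward_stepwise_select(X, y, k=5).features
        assert p1 == p2

    def test_insignificant_steps_flagged(self, rng):
        X = rng.normal(size=(30, 20))
        y = np.array([0, 1] * 15)
        path = forward_stepwise_select(X, y, k=10)
        assert len(path.flagged) == 10
        assert any(path.flagged)  # pure noise: most steps not significant


class TestMetrics:
    def test_stated_confusion_counts(self):
        # TP=6 FN=2 TN=7 FP=3
        t = [1] * 8 + [0] * 10
        p = [1] * 6 + [0] * 2 + [0] * 7 + [1] * 3
        m = classification_metrics(t, p, positive_class=1)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.70)
        assert m["accuracy"] == pytest.approx(13 / 18)
        assert m["f1"] == pytest.approx(12 / 17)

    def test_perfect_and_degenerate(self):
        m = classification_metrics([1, 0], [1, 0])
        assert m["accuracy"] == m["f1"] == 1.0
        m = classification_metrics([1, 0, 1, 0], [1, 1, 1, 1])
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0
        assert m["accuracy"] == 0.5

    def test_f1_formula(self):
        # TP=3 FP=1 TN=4 FN=2 -> F1 = 6/9
        t = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        p = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        assert classification_metrics(t, p)["f1"] == pytest.approx(2 / 3)


class TestLoso:
    def test_fold_purity_instrumented(self, monkeypatch):
        """The held-out subject's row must never reach scaler or selection."""
        X, y, _ = simulate_prediction_dataset(10, 6, n_informative=2, seed=0)
        seen_scaler_rows = []
        seen_select_rows = []
        orig_scaler = pred._fit_scaler
        orig_select = pred.forward_stepwise_select

        def spy_scaler(data):
            seen_scaler_rows.append(data.shape[0])
            return orig_scaler(data)

        def spy_select(Z, yy, **kw):
            seen_select_rows.append(Z.shape[0])
            return orig_select(Z, yy, **kw)

        monkeypatch.setattr(pred, "_fit_scaler", spy_scaler)
        monkeypatch.setattr(pred, "forward_stepwise_select", spy_select)
        loso_cv_predict(X, y, k=2)
        assert seen_scaler_rows == [9] * 10
        assert seen_select_rows == [9] * 10

    def test_one_fold_per_subject(self):
        X, y, _ = simulate_prediction_dataset(12, 8, n_informative=2, seed=1)
        report = loso_cv_predict(X, y, k=2)
        assert len(report.folds) == 12
        assert report.folds["subject_id"].is_unique

    def test_strong_signal_learned(self):
        X, y, _ = simulate_prediction_dataset(24, 30, n_informative=4, separation=2.5, seed=3)
        report = loso_cv_predict(X, y, k=4)
        assert report.metrics["accuracy"] >= 0.8

    def test_metrics_recomputable_from_folds(self):
        X, y, _ = simulate_prediction_dataset(14, 10, n_informative=2, seed=4)
        report = loso_cv_predict(X, y, k=2)
        again = classification_metrics(
            report.folds["true_label"], report.folds["predicted_label"], positive_class=1
        )
        assert again == report.metrics


class TestTransfer:
    def test_external_identical_to_training(self):
        X, y, names = simulate_prediction_dataset(20, 15, n_informative=3, seed=5)
        df = pd.DataFrame(X, columns=names)
        out = transfer_predict(df, y, df.copy(), k=3, external_y=y)
        # identical inputs: predictions equal the in-sample predictions
        mean = X.mean(0)
        std = np.where(X.std(0) > 0, X.std(0), 1.0)
        sel = [names.index(f) for f in out["selected"]]
        scores = ((X - mean) / std)[:, sel] @ out["weights"]
        assert (out["predicted"] == (scores > 0).astype(int)).all()

    def test_missing_features_imputed_as_zero(self):
        X, y, names = simulate_prediction_dataset(20, 15, n_informative=3, seed=6)
        df = pd.DataFrame(X, columns=names)
        external = df.iloc[:5].drop(columns=names[:8])
        out = transfer_predict(df, y, external, k=3)
        assert len(out["predicted"]) == 5

    def test_no_overlap_rejected(self):
        X, y, names = simulate_prediction_dataset(10, 5, seed=7)
        df = pd.DataFrame(X, columns=names)
        external = pd.DataFrame(np.zeros((3, 2)), columns=["other1", "other2"])
        with pytest.raises(ValueError):
            transfer_predict(df, y, external, k=2)

    def test_feature_filter_restricts_candidates(self):
        X, y, names = simulate_prediction_dataset(20, 15, n_informative=3, seed=8)
        df = pd.DataFrame(X, columns=names)
        keep = names[5:10]  # exclude the informative block
        out = transfer_predict(df, y, df.copy(), feature_filter=keep, k=2)
        assert set(out["selected"]) <= set(keep)
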