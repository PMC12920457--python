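"""Random-forest calibration and the R^2 / RMSE / RPD formulas."""

import types

import numpy as np
import pandas as pd
import pytest

from tanninspec import (
    RFConfig,
    RandomForestCalibrator,
    TanninTable,
    compare_inputs,
    evaluate,
    fit_rf,
    split,
)

FAST = RFConfig(n_trees=30, tuning_iterations=2, cv_folds=3, seed=0)


def _stub(predictions):
    return types.SimpleNamespace(predict=lambda X: np.asarray(predictions))


def test_protocol_defaults_echoed():
    cfg = RFConfig()
    assert cfg.n_trees == 200
    assert cfg.min_leaf == 10
    assert cfg.tuning_iterations == 50
    assert cfg.cv_folds == 5
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 4))
    model = fit_rf(X, X[:, 0] + rng.normal(0, 0.1, 30), FAST)
    assert model.config_echo_["n_trees"] == 30
    assert model.config_echo_["cv_folds"] == 3


def test_constant_target_predicts_constant():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 3))
    model = fit_rf(X, np.full(20, 7.5), FAST)
    np.testing.assert_allclose(model.predict(X), 7.5)


def test_noiseless_step_function_learned():
    rng = np.random.default_rng(2)
    X = rng.uniform(0, 1, (200, 5))
    y = np.where(X[:, 0] > 0.5, 10.0, 2.0)
    cfg = RFConfig(n_trees=50, min_leaf=1, tuning_iterations=0, cv_folds=3, seed=0,
                   feature_fraction_range=(1.0, 1.0))
    model = fit_rf(X, y, cfg)
    m = evaluate(model, X, y)
    assert m.r2 >= 0.99


def test_nonfinite_features_rejected():
    X = np.ones((10, 2))
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        fit_rf(X, np.arange(10.0), FAST)


class TestEvaluate:
    def test_hand_vectors(self):
        m = evaluate(_stub([1.0, 2.0, 4.0]), np.zeros((3, 1)), [1.0, 2.0, 3.0])
        assert m.rmse == pytest.approx(np.sqrt(1.0 / 3.0))
        assert m.r2 == pytest.approx(0.5)
        assert m.rpd == pytest.approx(1.0 / np.sqrt(1.0 / 3.0))

    def test_perfect_predictions(self):
        y = [1.0, 2.0, 3.0]
        with pytest.warns(RuntimeWarning, match="RPD"):
            m = evaluate(_stub(y), np.zeros((3, 1)), y)
        assert m.r2 == 1.0 and m.rmse == 0.0 and np.isinf(m.rpd)

    def test_mean_predictor(self, rng):
        y = rng.uniform(5, 20, 30)
        m = evaluate(_stub(np.full(30, y.mean())), np.zeros((30, 1)), y)
        assert m.r2 == pytest.approx(0.0, abs=1e-12)
        assert m.rpd == pytest.approx(np.sqrt(30 / 29))

    def test_order_invariance(self, rng):
        y = rng.uniform(5, 20, 25)
        pred = y + rng.normal(0, 1, 25)
        perm = rng.permutation(25)
        a = evaluate(_stub(pred), np.zeros((25, 1)), y)
        b = evaluate(_stub(pred[perm]), np.zeros((25, 1)), y[perm])
        assert a.r2 == pytest.approx(b.r2)
        assert a.rmse == pytest.approx(b.rmse)
        assert a.rpd == pytest.approx(b.rpd)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            evaluate(_stub([1.0, 1.0]), np.zeros((2, 1)), [3.0, 3.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(_stub([]), np.zeros((0, 1)), [])


class TestCompareInputs:
    def _toy(self, rng, n=40):
        ids = np.arange(1, n + 1)
        y = rng.uniform(5, 20, n)
        informative = y[:, None] * rng.uniform(0.5, 1.0, 4)[None, :] + rng.normal(0, 0.4, (n, 4))
        noise = rng.normal(size=(n, 16))
        X = np.c_[informative, noise]
        return X, ids, TanninTable(pd.Series(y, index=ids))

    def test_row_structure_and_determinism(self, rng):
        X, ids, tt = self._toy(rng)
        sp = split(ids, seed=0)
        feats = {"A": (X, ids), "B": (X.copy(), ids)}
        table = compare_inputs(feats, tt, sp, rf_cfg=FAST)
        # 2 inputs x 2 band modes x 2 sets
        assert len(table) == 8
        assert set(table["band_mode"]) == {"full", "characteristic"}
        a = table[table["input"] == "A"].drop(columns="input").reset_index(drop=True)
        b = table[table["input"] == "B"].drop(columns="input").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_characteristic_uses_fewer_features(self, rng):
        X, ids, tt = self._toy(rng)
        sp = split(ids, seed=0)
        table = compare_inputs({"A": (X, ids)}, tt, sp, rf_cfg=FAST)
        n_char = table.loc[table["band_mode"] == "characteristic", "n_features"].iloc[0]
        n_full = table.loc[table["band_mode"] == "full", "n_features"].iloc[0]
        assert n_char < n_full

    def test_models_returned_on_request(self, rng):
        X, ids, tt = self._toy(rng)
        sp = split(ids, seed=0)
        table, models = compare_inputs({"A": (X, ids)}, tt, sp, rf_cfg=FAST, return_models=True)
        assert ("A", "full") in models and ("A", "characteristic") in models
        assert isinstance(models[("A", "full")]["model"], RandomForestCalibrator)


def test_save_load_round_trip(rng, tmp_path):
    X = rng.normal(size=(30, 4))
    y = X[:, 0] + rng.normal(0, 0.1, 30)
    model = fit_rf(X, y, FAST)
    path = tmp_path / "model.joblib"
    model.save(path)
    from tanninspec import RandomForestCalibrator

    back = RandomForestCalibrator.load(path)
    np.testing.assert_allclose(back.predict(X), model.predict(X))
    assert back.config_echo_ == model.config_echo_


def test_calibrator_is_sklearn_estimator(rng):
    from sklearn.base import clone

    est = RandomForestCalibrator(n_trees=20, min_leaf=2, tuning_iterations=0, cv_folds=2, seed=0)
    clone(est)
    X = rng.normal(size=(40, 3))
    y = X[:, 0] + rng.normal(0, 0.1, 40)
    est.fit(X, y)
    assert hasattr(est, "model_") and hasattr(est, "best_params_")
    assert est.score(X, y) > 0.3  # RegressorMixin R^2
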