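"""Random-forest calibration with R^2 / RMSE / RPD evaluation.

The forest uses the study protocol's hyperparameters (200 trees, minimum
leaf size 10) with a seeded sequential random search (default budget 50
evaluations, 5-fold CV, objective = mean CV RMSE) over the per-split
feature fraction and, optionally, the minimum leaf size.  RPD is the sample
standard deviation (n-1) of the evaluated set's reference values divided by
the RMSE; RPD > 2.0 is the conventional robustness bar, 1.4-2.0 moderate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = ["RFConfig", "CalibrationMetrics", "RandomForestCalibrator", "fit_rf", "evaluate", "compare_inputs"]


@dataclass
class RFConfig:
    n_trees: int = 200
    min_leaf: int = 10
    tuning_iterations: int = 50
    cv_folds: int = 5
    feature_fraction_range: tuple = (0.05, 1.0)
    min_leaf_range: tuple = None  # e.g. (4, 16); None => keep min_leaf fixed
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_trees, self.min_leaf, self.cv_folds) < 1 or self.tuning_iterations < 0:
            raise ValueError("counts must be positive (tuning_iterations may be 0)")


@dataclass
class CalibrationMetrics:
    r2: float
    rmse: float
    rpd: float
    n: int

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "rpd": self.rpd, "n": self.n}


class RandomForestCalibrator(BaseEstimator, RegressorMixin):
    """Tuned random-forest regressor for spectral calibration.

    Fitted attributes: ``model_`` (the final RandomForestRegressor),
    ``best_params_``, ``cv_results_`` (DataFrame of the search trace) and
    ``config_echo_`` (the hyperparameters actually used).
    """

    def __init__(self, n_trees=200, min_leaf=10, tuning_iterations=50, cv_folds=5,
                 feature_fraction_range=(0.05, 1.0), min_leaf_range=None, seed=0):
        self.n_trees = n_trees
        self.min_leaf = min_leaf
        self.tuning_iterations = tuning_iterations
        self.cv_folds = cv_folds
        self.feature_fraction_range = feature_fraction_range
        self.min_leaf_range = min_leaf_range
        self.seed = seed

    def _forest(self, max_features, min_leaf, seed) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            min_samples_leaf=min_leaf,
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        n = X.shape[0]
        folds = min(self.cv_folds, n)
        if n < folds:
            raise ValueError("fewer samples than CV folds")

        rng = np.random.default_rng(self.seed)
        lo, hi = self.feature_fraction_range
        candidates = []
        for _ in range(int(self.tuning_iterations)):
            frac = float(rng.uniform(lo, hi))
            leaf = self.min_leaf
            if self.min_leaf_range is not None:
                leaf = int(rng.integers(self.min_leaf_range[0], self.min_leaf_range[1] + 1))
            candidates.append({"max_features": frac, "min_samples_leaf": leaf})
        if not candidates:
            # untuned: midpoint of the declared fraction range
            candidates = [{"max_features": 0.5 * (lo + hi), "min_samples_leaf": self.min_leaf}]

        kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        fit_seed = int(rng.integers(2**31 - 1))
        trace = []
        best_rmse, best = np.inf, None
        for cand in candidates:
            errs = []
            for tr, va in kf.split(X):
                model = self._forest(cand["max_features"], cand["min_samples_leaf"], fit_seed)
                model.fit(X[tr], y[tr])
                pred = model.predict(X[va])
                errs.append(np.sqrt(np.mean((pred - y[va]) ** 2)))
            rmse = float(np.mean(errs))
            trace.append({**cand, "cv_rmse": rmse})
            if rmse < best_rmse:
                best_rmse, best = rmse, cand

        self.model_ = self._forest(best["max_features"], best["min_samples_leaf"], fit_seed)
        self.model_.fit(X, y)
        self.best_params_ = dict(best)
        self.cv_results_ = pd.DataFrame(trace)
        self.config_echo_ = {
            "n_trees": self.n_trees,
            "min_leaf": self.min_leaf,
            "tuning_iterations": self.tuning_iterations,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
        }
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))

    def save(self, path) -> None:
        """Persist the fitted calibrator (self-describing: config echo and
        tuning trace travel with the model)."""
        joblib.dump(
            {"calibrator": self, "config_echo": self.config_echo_, "best_params": self.best_params_},
            path,
        )

    @staticmethod
    def load(path) -> "RandomForestCalibrator":
        payload = joblib.load(path)
        return payload["calibrator"]


def fit_rf(X_train, y_train, cfg: RFConfig = None) -> RandomForestCalibrator:
    cfg = cfg or RFConfig()
    cfg.validate()
    return RandomForestCalibrator(
        n_trees=cfg.n_trees,
        min_leaf=cfg.min_leaf,
        tuning_iterations=cfg.tuning_iterations,
        cv_folds=cfg.cv_folds,
        feature_fraction_range=cfg.feature_fraction_range,
        min_leaf_range=cfg.min_leaf_range,
        seed=cfg.seed,
    ).fit(X_train, y_train)


def evaluate(model, X, y) -> CalibrationMetrics:
    """R^2, RMSE (mg/g) and RPD of ``model`` on an evaluation set.

    R^2 = 1 - SSE/SST; RPD = sd(y, ddof=1) / RMSE.  A perfect fit reports
    RPD = inf with a warning; a constant reference set is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty evaluation set")
    if np.ptp(y) == 0:
        raise ValueError("constant reference values: RPD undefined")
    pred = np.asarray(model.predict(X), dtype=float)
    resid = y - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst
    sd = float(np.std(y, ddof=1))
    if rmse == 0.0:
        warnings.warn("RMSE is zero; reporting RPD as +inf", RuntimeWarning, stacklevel=2)
        rpd = np.inf
    else:
        rpd = sd / rmse
    return CalibrationMetrics(r2=r2, rmse=rmse, rpd=rpd, n=int(y.size))


def compare_inputs(
    feature_sets: dict,
    y_by_id,
    split_result,
    rf_cfg: RFConfig = None,
    selector_factory=None,
    band_modes=("full", "characteristic"),
    overfit_margin: float = 0.15,
    return_models: bool = False,
):
    """Fit one forest per (input definition, band mode) on a shared split.

    ``feature_sets`` maps input name -> (X matrix aligned to ``ids``, ids).
    ``y_by_id`` is a TanninTable-like object with ``values_for``.
    ``selector_factory`` builds the characteristic-band selector (default
    :class:`~tanninspec.selection.CorrelationBandSelector` at alpha 0.01);
    selection is fitted on all samples, as in the study protocol.
    Returns a tidy table with one row per (input, band_mode, set).
    """
    from .selection import CorrelationBandSelector

    rf_cfg = rf_cfg or RFConfig()
    rf_cfg.validate()
    if selector_factory is None:
        selector_factory = lambda: CorrelationBandSelector(alpha=0.01)

    rows = []
    models = {}
    for name, (X, ids) in feature_sets.items():
        ids = np.asarray(ids)
        y = y_by_id.values_for(ids)
        tr_mask = np.isin(ids, split_result.train_ids)
        va_mask = np.isin(ids, split_result.val_ids)
        for mode in band_modes:
            if mode == "characteristic":
                sel = selector_factory().fit(X, y)
                Xm = sel.transform(X)
                n_features = int(Xm.shape[1])
                if n_features == 0:
                    logger.warning("%s: no characteristic bands selected; skipping", name)
                    continue
            else:
                sel = None
                Xm, n_features = X, int(X.shape[1])
            model = fit_rf(Xm[tr_mask], y[tr_mask], rf_cfg)
            models[(name, mode)] = {"model": model, "selector": sel, "X": Xm, "ids": ids, "y": y}
            m_tr = evaluate(model, Xm[tr_mask], y[tr_mask])
            m_va = evaluate(model, Xm[va_mask], y[va_mask])
            overfit = (m_tr.r2 - m_va.r2) > overfit_margin
            for set_name, m in (("train", m_tr), ("val", m_va)):
                rows.append(
                    {
                        "input": name,
                        "band_mode": mode,
                        "set": set_name,
                        "n_features": n_features,
                        "overfit_flag": overfit,
                        **m.as_dict(),
                    }
                )
    table = pd.DataFrame(rows)
    if return_models:
        return table, models
    return table
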