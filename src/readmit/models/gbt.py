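"""Gradient-boosted trees (XGBoost) on dummy-coded code indicators.

Uses the conservative learning rate 0.0002; because each boosting round
then moves the margin very little, the default round cap is high and the
number of rounds is chosen by early stopping on the validation split.
No hospital effect: the hospital assignment is ignored at prediction.
"""

from __future__ import annotations

import numpy as np
import xgboost as xgb

from .base import HospitalAssignment, InputError, RiskModel, _check_probabilities

__all__ = ["GBTModel", "fit_gbt"]


class GBTModel(RiskModel):
    model_kind = "GBT"
    has_hospital_effect = False

    def __init__(self, booster: xgb.Booster, best_iteration: int):
        self.booster = booster
        self.best_iteration = best_iteration

    def predict(self, inputs, assignment=HospitalAssignment.ACTUAL) -> np.ndarray:
        dm = xgb.DMatrix(inputs)
        if self.booster.num_boosted_rounds() == 0:
            p = self.booster.predict(dm)  # base score only
        else:
            p = self.booster.predict(
                dm, iteration_range=(0, self.best_iteration + 1))
        return _check_probabilities(np.asarray(p, dtype=float))


def fit_gbt(X_train, y_train, X_val, y_val,
            learning_rate: float = 0.0002,
            n_rounds: int = 20000,
            early_stopping_rounds: int = 50,
            max_depth: int = 6,
            seed: int = 0,
            nthread: int = 1) -> GBTModel:
    """Fit the boosted-tree model with validation-based early stopping."""
    if X_train.shape[0] == 0 or X_train.shape[1] == 0:
        raise InputError("empty feature matrix")
    dtrain = xgb.DMatrix(X_train, label=np.asarray(y_train))
    dval = xgb.DMatrix(X_val, label=np.asarray(y_val))
    # early stopping watches validation logloss: with the conservative
    # learning rate the AUC moves too slowly between rounds to register
    # improvement, while logloss decreases monotonically along the descent
    params = {
        "objective": "binary:logistic",
        "eta": learning_rate,
        "max_depth": max_depth,
        "eval_metric": "logloss",
        "tree_method": "hist",
        "nthread": nthread,
        "seed": seed,
    }
    if n_rounds == 0:
        booster = xgb.train(params, dtrain, num_boost_round=0)
        return GBTModel(booster, 0)
    evals_result: dict = {}
    booster = xgb.train(params, dtrain, num_boost_round=n_rounds,
                        evals=[(dval, "validation")],
                        early_stopping_rounds=early_stopping_rounds,
                        evals_result=evals_result, verbose_eval=False)
    best_it = getattr(booster, "best_iteration", None)
    if best_it is None:
        best_it = n_rounds - 1
    return GBTModel(booster, int(best_it))
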