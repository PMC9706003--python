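"""Machine-learning prediction of individual tacrolimus clearance.

The downstream stage of the pipeline: once the population model has
screened the covariates, each subject's empirical-Bayes clearance
CL_i = TV_CL(covariates_i) * exp(eta_hat_CL,i) becomes the regression
target, and the screened covariates (age plus the Wuzhi, CYP3A5 *3/*3
and CTLA4 level indicators) the features.

Protocol: five outer repetitions of {fresh random 70/30 train/test
split; 5-fold cross-validated hyperparameter grid search on the training
70%; refit the best configuration on the full training set; score on the
held-out 30%}; the report averages the five test-set scores.

Metrics: R^2, MSE, MAE, MedAE, RE = mean(|y - yhat| / y) (mean relative
error), and RMSE.  RE is reported as relative error because a
root-mean-square reading is arithmetically inconsistent with reporting
MSE alongside it; both quantities are emitted so either convention can
be read off.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import Lasso
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from xgboost import XGBRegressor

from .events import EventTable
from .foce import FitResult
from .model import covariate_factors

__all__ = ["ALGORITHMS", "build_ml_table", "regression_metrics", "run_protocol"]

#: default feature set: the PPK-screened covariates
DEFAULT_FEATURES = ("AGE", "COMBWZ", "CYP3A5_33", "CTLA4_GA", "CTLA4_AA")

#: algorithm families and their (deliberately small) hyperparameter grids
ALGORITHMS: dict = {
    "XGBoost": (
        lambda seed: XGBRegressor(
            objective="reg:squarederror", random_state=seed, n_jobs=1,
            verbosity=0,
        ),
        {"n_estimators": [50, 150], "max_depth": [2, 3],
         "learning_rate": [0.1, 0.3]},
    ),
    "RF": (
        lambda seed: RandomForestRegressor(random_state=seed, n_jobs=1),
        {"n_estimators": [100, 300], "max_depth": [None, 4]},
    ),
    "Extra-Trees": (
        lambda seed: ExtraTreesRegressor(random_state=seed, n_jobs=1),
        {"n_estimators": [100, 300], "max_depth": [None, 4]},
    ),
    "GBDT": (
        lambda seed: GradientBoostingRegressor(random_state=seed),
        {"n_estimators": [50, 150], "max_depth": [2, 3]},
    ),
    "AdaBoost": (
        lambda seed: AdaBoostRegressor(random_state=seed),
        {"n_estimators": [50, 100], "learning_rate": [0.5, 1.0]},
    ),
    "Lasso": (
        lambda seed: Lasso(max_iter=50000, random_state=seed),
        {"alpha": list(np.logspace(-4, 0, 9))},
    ),
}


def build_ml_table(fit: FitResult, table: EventTable,
                   features=DEFAULT_FEATURES) -> pd.DataFrame:
    """One row per subject: screened covariate features + EBE clearance target.

    The target is the individual clearance of the fitted population model,
    CL_i = TV_CL * covariate factors * exp(eta_hat_CL,i).  Subjects with a
    missing feature are excluded.
    """
    table = table.with_indicators()
    cov = table.covariates()
    spec = fit.spec
    fcl, _ = covariate_factors(spec, cov)
    ebes = fit.ebes.set_index("ID")
    eta_cl = ebes.loc[cov["ID"], "eta_cl"].to_numpy()
    out = cov[["ID"]].copy()
    for feat in features:
        out[feat] = cov[feat] if feat in cov.columns else np.nan
    out["CL"] = spec.tv_cl * fcl * np.exp(eta_cl)
    out = out.dropna()
    return out.reset_index(drop=True)


def regression_metrics(y, yhat) -> dict:
    """R^2, MSE, MAE, MedAE, RE (mean relative error) and RMSE."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape or len(y) < 2:
        raise ValueError("need equal-length arrays with >= 2 points")
    res = y - yhat
    ss_res = float(np.sum(res ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    nz = y != 0
    if not nz.all():
        import warnings

        warnings.warn("zero targets excluded from relative error")
    return {
        "R2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        "MSE": float(np.mean(res ** 2)),
        "MAE": float(np.mean(np.abs(res))),
        "MedAE": float(np.median(np.abs(res))),
        "RE": float(np.mean(np.abs(res[nz]) / y[nz])) if nz.any() else np.nan,
        "RMSE": float(np.sqrt(np.mean(res ** 2))),
    }


def run_protocol(ml_table: pd.DataFrame, algorithms=None, seed=0,
                 n_repeats=5, test_size=0.3, cv_folds=5,
                 features=None) -> pd.DataFrame:
    """Repeated split + cross-validated grid search over algorithm families.

    Returns a report with one row per algorithm: the metric means over the
    ``n_repeats`` outer repetitions, plus the per-repetition chosen
    hyperparameters in the ``chosen`` column.
    """
    if len(ml_table) < 30:
        raise ValueError("protocol needs >= 30 subjects")
    algorithms = algorithms or ALGORITHMS
    features = list(features) if features else [
        c for c in ml_table.columns if c not in ("ID", "CL")
    ]
    X = ml_table[features].to_numpy(dtype=float)
    y = ml_table["CL"].to_numpy(dtype=float)
    rows = []
    for name, (factory, grid) in algorithms.items():
        per_rep, chosen, failed = [], [], 0
        for rep in range(n_repeats):
            rs = (seed * 1000 + rep) % (2 ** 31 - 1)
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=test_size, random_state=rs
            )
            try:
                search = GridSearchCV(
                    factory(rs), grid,
                    cv=KFold(cv_folds, shuffle=True, random_state=rs),
                    scoring="r2", n_jobs=1, refit=True,
                )
                search.fit(X_tr, y_tr)
                yhat = search.best_estimator_.predict(X_te)
            except Exception:
                failed += 1
                continue
            per_rep.append(regression_metrics(y_te, yhat))
            chosen.append(search.best_params_)
        if not per_rep:
            rows.append({"algorithm": name, "failed_repetitions": n_repeats})
            continue
        means = pd.DataFrame(per_rep).mean().to_dict()
        rows.append(
            {"algorithm": name, **means, "failed_repetitions": failed,
             "chosen": chosen}
        )
    return pd.DataFrame(rows)
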