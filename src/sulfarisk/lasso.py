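"""L1-penalized regression with leave-one-out penalty selection.

Objective per grid point (glmnet / scikit-learn convention):

    (1 / 2n) * Σ_i (y_i - β0 - x_i·β)² + λ * Σ_j |β_j|

The intercept is unpenalized.  The penalty weight λ is chosen on a decreasing
100-point log grid from λ_max (smallest λ that zeroes every coefficient) down
to 1e-4·λ_max by minimizing the mean leave-one-out squared error, refitting
imputation and scaling inside every fold; ties are broken toward the larger
(sparser) λ.  The final model cannot select more descriptors than training
observations — the l1 path never activates more variables than rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import Lasso

from .feature_schema import FeatureTable
from .preprocessing import (
    ImputerState, ScalerState, apply_imputer, apply_scaler,
    fit_imputer, fit_scaler, prepare_fold_arrays,
)

__all__ = [
    "LassoFit",
    "lambda_max",
    "default_lambda_grid",
    "fit_lasso_path",
    "select_lambda_loo",
    "selected_descriptors",
    "predict_lasso",
]


@dataclass
class LassoFit:
    """Final LASSO model and its LOO path diagnostics."""

    lam: float
    intercept: float
    coefficients: dict[str, float]     # scaled descriptor space
    lambdas: np.ndarray
    loo_mse: np.ndarray
    nonzero_counts: np.ndarray
    imputer: ImputerState
    scaler: ScalerState

    def to_dict(self) -> dict:
        return {
            "lambda": float(self.lam),
            "intercept": float(self.intercept),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "lambda_grid": [float(v) for v in self.lambdas],
            "loo_mse": [float(v) for v in self.loo_mse],
            "nonzero_counts": [int(v) for v in self.nonzero_counts],
        }


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that shrinks every coefficient to zero:
    max_j |x_jᵀ(y - ȳ)| / n."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100,
                        eps: float = 1e-4) -> np.ndarray:
    """Decreasing log-spaced grid from λ_max down to eps·λ_max."""
    lmax = lambda_max(X, y)
    if lmax <= 0:
        lmax = 1.0  # constant response; grid value is irrelevant
    return np.geomspace(lmax, eps * lmax, n_lambdas)


def fit_lasso_path(X: np.ndarray, y: np.ndarray, lambdas: Sequence[float]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and intercepts along a decreasing λ grid (warm starts).

    Returns ``(coefs, intercepts)`` with ``coefs`` of shape (len(lambdas), p).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in LASSO inputs")
    lambdas = np.asarray(lambdas, float)
    if lambdas.ndim != 1 or lambdas.size == 0:
        raise ValueError("lambda grid must be a non-empty 1-D sequence")
    if np.any(lambdas <= 0) or np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be positive and strictly decreasing")

    est = Lasso(alpha=lambdas[0], fit_intercept=True, warm_start=True,
                max_iter=100_000, tol=1e-10)
    coefs = np.empty((lambdas.size, X.shape[1]))
    intercepts = np.empty(lambdas.size)
    for k, lam in enumerate(lambdas):
        est.set_params(alpha=lam)
        est.fit(X, y)
        coefs[k] = est.coef_
        intercepts[k] = est.intercept_
    return coefs, intercepts


def select_lambda_loo(table: FeatureTable, lambdas: Sequence[float] | None = None,
                      clip_negative: bool = True) -> LassoFit:
    """Choose λ by leave-one-out CV on the training rows and refit.

    Every fold refits imputation and scaling on its own training rows before
    computing the path; held-out predictions are clipped at 0 J/g.  The grid
    is fixed once from the full training set so fold errors are comparable.
    """
    train = table.train
    if len(train) < 3:
        raise ValueError("LOO lambda selection requires at least 3 training rows")
    ids = list(table.registry.ids)
    X_raw = train.X(ids)
    y = train.y_per_gram
    n = len(train)

    X_full, _, _, _ = prepare_fold_arrays(X_raw)
    grid = (np.asarray(lambdas, float) if lambdas is not None
            else default_lambda_grid(X_full, y))

    sq_errors = np.zeros(grid.size)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xt, Xo, _, _ = prepare_fold_arrays(X_raw[tr], X_raw[i:i + 1])
        coefs, intercepts = fit_lasso_path(Xt, y[tr], grid)
        pred = intercepts + coefs @ Xo[0]
        if clip_negative:
            pred = np.maximum(pred, 0.0)
        sq_errors += (pred - y[i]) ** 2
    loo_mse = sq_errors / n

    # ties toward larger λ: grid is decreasing, argmin takes first occurrence
    best_k = int(np.argmin(loo_mse))
    lam = float(grid[best_k])

    imputer = fit_imputer(train)
    completed = apply_imputer(imputer, train)
    scaler = fit_scaler(completed)
    scaled = apply_scaler(scaler, completed)
    coefs, intercepts = fit_lasso_path(scaled.X(ids), y, grid)
    nonzero_counts = np.count_nonzero(coefs, axis=1)
    return LassoFit(
        lam=lam, intercept=float(intercepts[best_k]),
        coefficients=dict(zip(ids, coefs[best_k])),
        lambdas=grid, loo_mse=loo_mse, nonzero_counts=nonzero_counts,
        imputer=imputer, scaler=scaler,
    )


def selected_descriptors(fit: LassoFit) -> tuple[str, ...]:
    """Descriptor ids with nonzero coefficients."""
    return tuple(k for k, v in fit.coefficients.items() if v != 0.0)


def predict_lasso(fit: LassoFit, table: FeatureTable,
                  clip_negative: bool = True) -> np.ndarray:
    """Predict per-gram enthalpies for the rows of ``table`` (J/g)."""
    scaled = apply_scaler(fit.scaler, apply_imputer(fit.imputer, table))
    ids = list(table.registry.ids)
    beta = np.array([fit.coefficients[i] for i in ids])
    pred = fit.intercept + scaled.X(ids) @ beta
    if clip_negative:
        pred = np.maximum(pred, 0.0)
    return pred
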