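"""Error metrics, thermal-criticality classification, DSC baseline and ensembling.

SEV and SEP are both root-mean-square errors (J/g), over the leave-one-out
cross-validation residuals and the prediction-set residuals respectively.
Thermal criticality follows the four Stoessel classes on released energy:
negligible (< 100 J/g, green), medium ([100, 400) J/g, yellow), critical
([400, 800) J/g, orange) and catastrophic (>= 800 J/g, red).  Boundary values
are assigned to the more severe class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_schema import DataError, FeatureTable

__all__ = [
    "CriticalityClass",
    "EvaluationResult",
    "CriticalityReport",
    "DscBaselineResult",
    "rmse",
    "r_squared",
    "evaluate",
    "classify_stoessel",
    "criticality_report",
    "dsc_baseline",
    "ensemble_mean",
    "enumerate_ensembles",
]


class CriticalityClass(IntEnum):
    """Stoessel thermal criticality classes, ordered by severity."""

    NEGLIGIBLE = 0
    MEDIUM = 1
    CRITICAL = 2
    CATASTROPHIC = 3

    @property
    def color(self) -> str:
        return ("green", "yellow", "orange", "red")[self.value]

    @property
    def label(self) -> str:
        return self.name.lower()


_CLASS_EDGES = (100.0, 400.0, 800.0)


def classify_stoessel(h: float) -> CriticalityClass:
    """Map a (non-negative) released energy in J/g to its criticality class."""
    if not np.isfinite(h) or h < 0:
        raise ValueError(f"enthalpy must be finite and >= 0 J/g, got {h}")
    for cls, edge in zip(CriticalityClass, _CLASS_EDGES):
        if h < edge:
            return cls
    return CriticalityClass.CATASTROPHIC


def rmse(measured, predicted) -> float:
    """Root-mean-square error sqrt(mean((ŷ - y)²))."""
    y = np.asarray(measured, float)
    yhat = np.asarray(predicted, float)
    if y.shape != yhat.shape:
        raise ValueError("measured and predicted must have equal length")
    if y.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def r_squared(measured, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (about measured mean)."""
    y = np.asarray(measured, float)
    yhat = np.asarray(predicted, float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined for a constant measured vector")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class EvaluationResult:
    """Per-compound predictions with summary statistics (J/g)."""

    compound_ids: tuple[str, ...]
    measured: np.ndarray
    predicted: np.ndarray
    rmse: float
    r2: float | None
    n: int


def evaluate(measured, predicted, compound_ids: Sequence[str] | None = None
             ) -> EvaluationResult:
    y = np.asarray(measured, float)
    yhat = np.asarray(predicted, float)
    ids = tuple(compound_ids) if compound_ids is not None else tuple(
        f"row{i}" for i in range(y.size))
    r2 = None
    if y.size >= 2 and np.ptp(y) > 0:
        r2 = r_squared(y, yhat)
    return EvaluationResult(ids, y, yhat, rmse(y, yhat), r2, int(y.size))


@dataclass
class CriticalityReport:
    """Measured vs predicted criticality classes per compound and model."""

    table: pd.DataFrame                       # compound_id, measured_class, <model>_class...
    misclassified: dict[str, tuple[str, ...]]
    counts: dict[str, int]


def criticality_report(compound_ids: Sequence[str], measured,
                       predictions: Mapping[str, Sequence[float]]
                       ) -> CriticalityReport:
    """Classify measured and per-model predicted enthalpies and tally
    misclassifications."""
    ids = list(compound_ids)
    y = np.asarray(measured, float)
    if len(ids) != y.size:
        raise ValueError("compound ids and measured values must align")
    rows = {"compound_id": ids,
            "measured_class": [classify_stoessel(v).label for v in y]}
    mis: dict[str, tuple[str, ...]] = {}
    counts: dict[str, int] = {}
    for model, pred in predictions.items():
        pred = np.asarray(pred, float)
        if pred.size != y.size:
            raise ValueError(f"predictions for {model!r} do not align with compounds")
        classes = [classify_stoessel(v) for v in pred]
        rows[f"{model}_class"] = [c.label for c in classes]
        wrong = tuple(
            cid for cid, c, v in zip(ids, classes, y)
            if c != classify_stoessel(v)
        )
        mis[model] = wrong
        counts[model] = len(wrong)
    return CriticalityReport(pd.DataFrame(rows), mis, counts)


@dataclass
class DscBaselineResult:
    """Univariate regression of enthalpy on the summed DSC event enthalpy."""

    slope: float
    intercept: float
    r2_train: float
    sev: float
    sep: float | None
    train_eval: EvaluationResult
    predict_eval: EvaluationResult | None


def _simple_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return 0.0, float(y.mean())
    slope = float(xc @ (y - y.mean())) / denom
    return slope, float(y.mean() - slope * x.mean())


def dsc_baseline(table: FeatureTable, column: str = "DSC_Sum_dH",
                 clip_negative: bool = True) -> DscBaselineResult:
    """Baseline: predict reaction enthalpy from DSC screening data alone.

    Ordinary least squares of the per-gram enthalpy on the summed DSC event
    enthalpy column, fitted on the training rows; SEV by leave-one-out
    refitting, SEP on the prediction set, R² on the training fit.
    """
    if column not in table.registry:
        raise DataError(f"DSC column {column!r} not in registry")
    train = table.train
    x = train.df[column].to_numpy(float)
    y = train.y_per_gram
    if np.any(~np.isfinite(x)):
        raise DataError(f"missing values in DSC column {column!r}")
    if len(train) < 3:
        raise ValueError("baseline requires at least 3 training rows")

    slope, intercept = _simple_ols(x, y)
    fitted = intercept + slope * x
    r2_train = r_squared(y, fitted)

    n = y.size
    loo_res = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        s, b = _simple_ols(x[tr], y[tr])
        pred = b + s * x[i]
        if clip_negative:
            pred = max(pred, 0.0)
        loo_res[i] = pred - y[i]
    sev = float(np.sqrt(np.mean(loo_res**2)))

    sep = None
    predict_eval = None
    pred_tab = table.predict
    if len(pred_tab) > 0:
        xp = pred_tab.df[column].to_numpy(float)
        if np.any(~np.isfinite(xp)):
            raise DataError(f"missing values in DSC column {column!r}")
        yp_hat = intercept + slope * xp
        if clip_negative:
            yp_hat = np.maximum(yp_hat, 0.0)
        predict_eval = evaluate(pred_tab.y_per_gram, yp_hat, pred_tab.compound_ids)
        sep = predict_eval.rmse

    return DscBaselineResult(
        slope=slope, intercept=intercept, r2_train=r2_train, sev=sev, sep=sep,
        train_eval=evaluate(y, np.maximum(fitted, 0.0) if clip_negative else fitted,
                            train.compound_ids),
        predict_eval=predict_eval,
    )


def ensemble_mean(predictions: Mapping[str, Sequence[float]],
                  subset: Sequence[str]) -> np.ndarray:
    """Equal-weight mean of the member models' per-compound predictions."""
    subset = list(subset)
    if not subset:
        raise ValueError("ensemble subset must be non-empty")
    mats = []
    length = None
    for model in subset:
        pred = np.asarray(predictions[model], float)
        if length is None:
            length = pred.size
        elif pred.size != length:
            raise ValueError("all models must predict the same compounds")
        mats.append(pred)
    return np.mean(mats, axis=0)


def enumerate_ensembles(measured, predictions: Mapping[str, Sequence[float]],
                        model_order: Sequence[str] | None = None) -> pd.DataFrame:
    """All 2^k - 1 non-empty model combinations with their SEP and R².

    Rows are ordered by decreasing ensemble size, then by member precedence,
    mirroring the usual combination-table layout.
    """
    models = list(model_order) if model_order is not None else list(predictions)
    y = np.asarray(measured, float)
    rows = []
    for size in range(len(models), 0, -1):
        for combo in itertools.combinations(models, size):
            pred = ensemble_mean(predictions, combo)
            row = {m: (m in combo) for m in models}
            row["sep"] = rmse(y, pred)
            row["r2"] = r_squared(y, pred) if y.size >= 2 and np.ptp(y) > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
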