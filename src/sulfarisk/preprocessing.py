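"""Training-set-derived imputation, autoscaling and enthalpy unit conversion.

All models share the same protocol: missing descriptor cells (undefined C–H
bond energies / H-site properties) are replaced by the mean of the observed
values in the *training* rows, then every descriptor column is mean-centered
and scaled to unit sample standard deviation using training statistics.
Inside cross-validation both states are refitted on each fold's training rows
so no information leaks from the held-out compound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_schema import DataError, FeatureTable

__all__ = [
    "ImputerState",
    "ScalerState",
    "fit_imputer",
    "apply_imputer",
    "fit_scaler",
    "apply_scaler",
    "per_gram_to_per_mol",
    "per_mol_to_per_gram",
    "prepare_fold_arrays",
]


@dataclass
class ImputerState:
    """Per-column training means for the columns that may contain gaps."""

    means: dict[str, float]

    def to_dict(self) -> dict:
        return {"means": dict(self.means)}

    @classmethod
    def from_dict(cls, d: dict) -> "ImputerState":
        return cls(means={k: float(v) for k, v in d["means"].items()})


@dataclass
class ScalerState:
    """Per-column training mean and sample (n-1) standard deviation."""

    mean: dict[str, float]
    sd: dict[str, float]

    def to_dict(self) -> dict:
        return {"mean": dict(self.mean), "sd": dict(self.sd)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerState":
        return cls(mean={k: float(v) for k, v in d["mean"].items()},
                   sd={k: float(v) for k, v in d["sd"].items()})


def fit_imputer(train: FeatureTable) -> ImputerState:
    """Mean of observed training values for every ``allow_missing`` column."""
    means: dict[str, float] = {}
    for col in train.registry.allow_missing_ids():
        vals = train.df[col].to_numpy(float)
        obs = vals[np.isfinite(vals)]
        if obs.size == 0:
            raise DataError(f"column {col!r} has no observed training values")
        means[col] = float(obs.mean())
    return ImputerState(means)


def apply_imputer(state: ImputerState, table: FeatureTable) -> FeatureTable:
    """Fill every missing cell with its TRAIN mean; observed cells untouched."""
    df = table.df.copy()
    for col in table.registry.ids:
        vals = df[col].to_numpy(float)
        gaps = ~np.isfinite(vals)
        if not gaps.any():
            continue
        if col not in state.means:
            raise DataError(f"missing cell in column {col!r} without a fitted mean")
        vals = vals.copy()
        vals[gaps] = state.means[col]
        df[col] = vals
    return FeatureTable(table.registry, df, validate=False)


def fit_scaler(train: FeatureTable) -> ScalerState:
    """Training mean/sd per descriptor column (imputation must be done first)."""
    mean, sd = {}, {}
    for col in train.registry.ids:
        vals = train.df[col].to_numpy(float)
        if np.any(~np.isfinite(vals)):
            raise DataError(f"column {col!r} still has missing values; impute first")
        mean[col] = float(vals.mean())
        s = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        sd[col] = s
    return ScalerState(mean=mean, sd=sd)


def apply_scaler(state: ScalerState, table: FeatureTable) -> FeatureTable:
    """(x - train_mean) / train_sd; zero-variance columns pass through centered."""
    df = table.df.copy()
    for col in table.registry.ids:
        s = state.sd[col]
        df[col] = (df[col].to_numpy(float) - state.mean[col]) / (s if s > 0 else 1.0)
    return FeatureTable(table.registry, df, validate=False)


def per_gram_to_per_mol(h, mw):
    """Convert J/g to J/mol (h × mw)."""
    mw = np.asarray(mw, float)
    if np.any(mw <= 0):
        raise ValueError("molecular weight must be positive")
    return np.asarray(h, float) * mw


def per_mol_to_per_gram(h, mw):
    """Convert J/mol to J/g (h / mw)."""
    mw = np.asarray(mw, float)
    if np.any(mw <= 0):
        raise ValueError("molecular weight must be positive")
    return np.asarray(h, float) / mw


def prepare_fold_arrays(X_train: np.ndarray, X_other: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Fast array path used inside cross-validation loops.

    Imputes each column of ``X_train`` with its observed-value mean, applies
    the same fill to ``X_other``, then autoscales both with the training
    mean/sd (sample convention; zero-variance columns only centered).

    Returns ``(X_train_scaled, X_other_scaled, mean, sd)``.
    """
    Xt = np.array(X_train, float)
    Xo = None if X_other is None else np.array(X_other, float)
    for j in range(Xt.shape[1]):
        col = Xt[:, j]
        gaps = ~np.isfinite(col)
        obs = col[~gaps]
        if obs.size == 0:
            raise DataError(f"fold column {j} has no observed values")
        fill = obs.mean()  # training observed mean, used for both matrices
        if gaps.any():
            col[gaps] = fill
        if Xo is not None:
            og = ~np.isfinite(Xo[:, j])
            if og.any():
                Xo[og, j] = fill
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=1) if Xt.shape[0] > 1 else np.zeros(Xt.shape[1])
    denom = np.where(sd > 0, sd, 1.0)
    Xt = (Xt - mean) / denom
    if Xo is not None:
        Xo = (Xo - mean) / denom
    return Xt, Xo, mean, sd
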